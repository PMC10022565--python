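"""Domain types for all model parameters, tabular readers/writers and validation.

The microsimulation is parameterised by five tables:

* a cumulative-incidence table ``F_c,g,s(t)`` for eight diagnostic clusters
  on an annual age grid 1-30, disaggregated by gender and socioeconomic
  status (SES);
* Gompertz survival parameters for all-cause mortality by gender and
  disorder status (any disorder yet vs none);
* a utility table by gender, SES and disorder status;
* annual per-patient costs per cluster in three categories (healthcare,
  direct non-medical, indirect) plus the one-off per-student cost of the
  school-based intervention;
* scalar specifications of the intervention effect window and of the
  simulated population composition.

All tables are read and written as plain delimiter-separated text with one
row per cell, so parameter bundles are diff-able and language-neutral.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# Constants: clusters, strata, age grid
# --------------------------------------------------------------------------

#: The eight diagnostic clusters of mental disorders.
CLUSTERS: tuple[str, ...] = (
    "substance_use",
    "anxiety",
    "mood",
    "psychosis_personality",
    "conduct",
    "adhd",
    "eating",
    "self_harm",
)

#: Accepted aliases for cluster names in input files (case-insensitive).
CLUSTER_ALIASES: dict[str, str] = {
    "depression": "mood",
    "mood_disorders": "mood",
    "mood disorders": "mood",
    "psychosis": "psychosis_personality",
    "psychosis_and_personality_disorders": "psychosis_personality",
    "conduct_disorders": "conduct",
    "eating_disorders": "eating",
    "self-harm": "self_harm",
    "selfharm": "self_harm",
}

GENDERS: tuple[str, str] = ("female", "male")
SES_LEVELS: tuple[str, str] = ("low", "medium_high")
SES_ALIASES: dict[str, str] = {
    "medium-to-high": "medium_high",
    "medium_to_high": "medium_high",
    "high": "medium_high",
}

#: Disorder status levels used for mortality and utilities.
STATUSES: tuple[str, str] = ("none", "any")

#: Annual age grid (closed, integer years). F(0) = 0 by convention.
AGES: np.ndarray = np.arange(1, 31)
HORIZON: int = 30


class ParameterError(ValueError):
    """Structural problem in a parameter table."""


def canonical_cluster(name: str) -> str:
    """Map a cluster label (or accepted alias) to its canonical name."""
    key = str(name).strip().lower()
    key = CLUSTER_ALIASES.get(key, key)
    if key not in CLUSTERS:
        raise ParameterError(f"unknown cluster name: {name!r}")
    return key


def canonical_ses(name: str) -> str:
    key = str(name).strip().lower()
    key = SES_ALIASES.get(key, key)
    if key not in SES_LEVELS:
        raise ParameterError(f"unknown SES level: {name!r}")
    return key


def canonical_gender(name: str) -> str:
    key = str(name).strip().lower()
    if key not in GENDERS:
        raise ParameterError(f"unknown gender: {name!r}")
    return key


@dataclass(frozen=True)
class Stratum:
    """A gender x SES population stratum."""

    gender: str
    ses: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "gender", canonical_gender(self.gender))
        object.__setattr__(self, "ses", canonical_ses(self.ses))

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.gender}/{self.ses}"


#: The four strata, in (gender, ses) iteration order.
STRATA: tuple[Stratum, ...] = tuple(
    Stratum(g, s) for g in GENDERS for s in SES_LEVELS
)


# --------------------------------------------------------------------------
# Cumulative incidence table
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    """A single validation failure in a CIF table (data, not an exception)."""

    cluster: str
    gender: str
    ses: str
    age: int
    rule: str
    message: str


class CIFTable:
    """Cumulative incidence F_c,g,s(t) on the annual age grid 1..30.

    Internally a dense float array of shape
    ``(n_clusters, n_genders, n_ses, n_ages)``; ``curve`` returns the
    30-vector for one cluster/stratum (F at ages 1..30; F(0)=0 by
    convention and is not stored).
    """

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        expected = (len(CLUSTERS), len(GENDERS), len(SES_LEVELS), len(AGES))
        if values.shape != expected:
            raise ParameterError(
                f"CIFTable values must have shape {expected}, got {values.shape}"
            )
        self.values = values

    # -- construction -----------------------------------------------------

    @classmethod
    def zeros(cls) -> "CIFTable":
        return cls(np.zeros((len(CLUSTERS), len(GENDERS), len(SES_LEVELS), len(AGES))))

    # -- indexing ----------------------------------------------------------

    @staticmethod
    def _idx(cluster: str, stratum: Stratum) -> tuple[int, int, int]:
        return (
            CLUSTERS.index(canonical_cluster(cluster)),
            GENDERS.index(stratum.gender),
            SES_LEVELS.index(stratum.ses),
        )

    def curve(self, cluster: str, stratum: Stratum) -> np.ndarray:
        """F(t) for t = 1..30 for one cluster and stratum (read-only view)."""
        c, g, s = self._idx(cluster, stratum)
        v = self.values[c, g, s]
        v.flags.writeable = False
        return v

    def set_curve(self, cluster: str, stratum: Stratum, values: Iterable[float]) -> None:
        c, g, s = self._idx(cluster, stratum)
        arr = np.asarray(list(values), dtype=float)
        if arr.shape != (len(AGES),):
            raise ParameterError(f"curve must have {len(AGES)} annual values")
        self.values[c, g, s] = arr

    def copy(self) -> "CIFTable":
        return CIFTable(self.values.copy())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CIFTable) and np.array_equal(self.values, other.values)

    # -- tabular IO --------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ci, c in enumerate(CLUSTERS):
            for gi, g in enumerate(GENDERS):
                for si, s in enumerate(SES_LEVELS):
                    for ai, age in enumerate(AGES):
                        rows.append((c, g, s, int(age), self.values[ci, gi, si, ai]))
        return pd.DataFrame(rows, columns=["cluster", "gender", "ses", "age", "cif"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CIFTable":
        required = {"cluster", "gender", "ses", "age", "cif"}
        missing = required - set(frame.columns)
        if missing:
            raise ParameterError(f"CIF table missing columns: {sorted(missing)}")
        table = cls.zeros()
        seen = np.zeros(table.values.shape, dtype=bool)
        for row in frame.itertuples(index=False):
            c = CLUSTERS.index(canonical_cluster(row.cluster))
            g = GENDERS.index(canonical_gender(row.gender))
            s = SES_LEVELS.index(canonical_ses(row.ses))
            age = int(row.age)
            if not 1 <= age <= HORIZON:
                raise ParameterError(f"age {age} outside grid 1..{HORIZON}")
            table.values[c, g, s, age - 1] = float(row.cif)
            seen[c, g, s, age - 1] = True
        if not seen.all():
            c, g, s, a = (int(i[0]) for i in np.nonzero(~seen))
            raise ParameterError(
                "CIF table incomplete; first missing cell: "
                f"cluster={CLUSTERS[c]} gender={GENDERS[g]} ses={SES_LEVELS[s]} age={a + 1}"
            )
        return table

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "CIFTable":
        return cls.from_frame(pd.read_csv(path))

    # -- validation --------------------------------------------------------

    def validate(self) -> list[Violation]:
        return validate_cif(self)


def validate_cif(table: CIFTable) -> list[Violation]:
    """Check range, monotonicity and F(30) < 1 cell by cell.

    Violations are returned as data so that callers can report all problems
    at once; a flat year (F(t) = F(t+1)) is legal (a zero-incidence year).
    """
    out: list[Violation] = []
    v = table.values
    for ci, c in enumerate(CLUSTERS):
        for gi, g in enumerate(GENDERS):
            for si, s in enumerate(SES_LEVELS):
                curve = v[ci, gi, si]
                for ai, age in enumerate(AGES):
                    f = curve[ai]
                    if not 0.0 <= f <= 1.0:
                        out.append(Violation(c, g, s, int(age), "range",
                                             f"F({age})={f} outside [0, 1]"))
                    prev = curve[ai - 1] if ai > 0 else 0.0
                    if f < prev:
                        out.append(Violation(c, g, s, int(age), "monotone",
                                             f"F({age})={f} < F({age - 1})={prev}"))
                if curve[-1] >= 1.0:
                    out.append(Violation(c, g, s, HORIZON, "horizon",
                                         f"F({HORIZON})={curve[-1]} must be < 1"))
    return out


# --------------------------------------------------------------------------
# Gompertz survival parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Gompertz:
    """One Gompertz distribution, hazard h(t) = rate * exp(shape * t)."""

    shape: float
    rate: float

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ParameterError(f"Gompertz rate must be > 0, got {self.rate}")
        h110 = self.rate * np.exp(self.shape * 110.0)
        if not np.isfinite(h110):
            raise ParameterError("Gompertz hazard not finite on [0, 110]")


class GompertzParams:
    """Gompertz mortality parameters keyed by gender x disorder status."""

    def __init__(self, params: Mapping[tuple[str, str], Gompertz]):
        self._params: dict[tuple[str, str], Gompertz] = {}
        for (gender, status), dist in params.items():
            gender = canonical_gender(gender)
            if status not in STATUSES:
                raise ParameterError(f"unknown disorder status: {status!r}")
            self._params[(gender, status)] = dist
        missing = [
            (g, st) for g in GENDERS for st in STATUSES
            if (g, st) not in self._params
        ]
        if missing:
            raise ParameterError(f"Gompertz parameters missing for {missing}")

    def __getitem__(self, key: tuple[str, str]) -> Gompertz:
        gender, status = key
        return self._params[(canonical_gender(gender), status)]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GompertzParams) and self._params == other._params

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, st, self._params[(g, st)].shape, self._params[(g, st)].rate)
            for g in GENDERS for st in STATUSES
        ]
        return pd.DataFrame(rows, columns=["gender", "status", "shape", "rate"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GompertzParams":
        params = {
            (row.gender, row.status): Gompertz(float(row.shape), float(row.rate))
            for row in frame.itertuples(index=False)
        }
        return cls(params)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "GompertzParams":
        return cls.from_frame(pd.read_csv(path))


# --------------------------------------------------------------------------
# Utilities
# --------------------------------------------------------------------------

class UtilityTable:
    """Annual utility u(gender, ses, disorder status), dimensionless in [0, 1]."""

    def __init__(self, values: Mapping[tuple[str, str, str], float]):
        self._values: dict[tuple[str, str, str], float] = {}
        for (gender, ses, status), u in values.items():
            gender, ses = canonical_gender(gender), canonical_ses(ses)
            if status not in STATUSES:
                raise ParameterError(f"unknown disorder status: {status!r}")
            u = float(u)
            if not 0.0 <= u <= 1.0:
                raise ParameterError(f"utility {u} outside [0, 1]")
            self._values[(gender, ses, status)] = u
        for g in GENDERS:
            for s in SES_LEVELS:
                for st in STATUSES:
                    if (g, s, st) not in self._values:
                        raise ParameterError(f"utility missing for {(g, s, st)}")
                if self._values[(g, s, "any")] > self._values[(g, s, "none")]:
                    raise ParameterError(
                        f"u(any) > u(none) for stratum ({g}, {s})"
                    )

    def __call__(self, gender: str, ses: str, status: str) -> float:
        return self._values[(canonical_gender(gender), canonical_ses(ses), status)]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, UtilityTable) and self._values == other._values

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, s, st, self._values[(g, s, st)])
            for g in GENDERS for s in SES_LEVELS for st in STATUSES
        ]
        return pd.DataFrame(rows, columns=["gender", "ses", "status", "utility"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "UtilityTable":
        return cls({
            (row.gender, row.ses, row.status): float(row.utility)
            for row in frame.itertuples(index=False)
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "UtilityTable":
        return cls.from_frame(pd.read_csv(path))


# --------------------------------------------------------------------------
# Costs
# --------------------------------------------------------------------------

#: Annual per-patient cost categories, €/patient-year.
COST_CATEGORIES: tuple[str, ...] = ("healthcare", "direct_non_medical", "indirect")

#: Per-student cost of delivering the school-based intervention, €.
DEFAULT_INTERVENTION_COST_PER_STUDENT: float = 135.70


class CostTable:
    """Annual per-patient costs per cluster plus the per-student intervention cost."""

    def __init__(
        self,
        per_cluster: pd.DataFrame,
        intervention_cost_per_student: float = DEFAULT_INTERVENTION_COST_PER_STUDENT,
    ):
        missing_cols = set(COST_CATEGORIES) - set(per_cluster.columns)
        if missing_cols:
            raise ParameterError(f"cost table missing categories: {sorted(missing_cols)}")
        frame = per_cluster.copy()
        if "cluster" in frame.columns:
            frame = frame.set_index("cluster")
        frame.index = [canonical_cluster(c) for c in frame.index]
        missing = set(CLUSTERS) - set(frame.index)
        if missing:
            raise ParameterError(f"cost table missing clusters: {sorted(missing)}")
        frame = frame.loc[list(CLUSTERS), list(COST_CATEGORIES)].astype(float)
        if (frame.values < 0).any():
            raise ParameterError("costs must be >= 0")
        if intervention_cost_per_student < 0:
            raise ParameterError("intervention cost must be >= 0")
        self.per_cluster = frame
        self.intervention_cost_per_student = float(intervention_cost_per_student)

    def annual_cost(self, cluster: str, category: str) -> float:
        return float(self.per_cluster.at[canonical_cluster(cluster), category])

    def category_vector(self, category: str) -> np.ndarray:
        """Annual costs for one category, ordered as CLUSTERS."""
        return self.per_cluster[category].to_numpy()

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CostTable)
            and self.per_cluster.equals(other.per_cluster)
            and self.intervention_cost_per_student == other.intervention_cost_per_student
        )

    def to_frame(self) -> pd.DataFrame:
        return self.per_cluster.reset_index(names="cluster")

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(
        cls,
        path: str | Path,
        intervention_cost_per_student: float = DEFAULT_INTERVENTION_COST_PER_STUDENT,
    ) -> "CostTable":
        return cls(pd.read_csv(path), intervention_cost_per_student)


# --------------------------------------------------------------------------
# Effect and population specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Effect:
    """An intervention effect on one cluster: an odds ratio or a standardized
    mean difference."""

    kind: str  # "or" | "smd"
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("or", "smd"):
            raise ParameterError(f"effect kind must be 'or' or 'smd', got {self.kind!r}")
        if self.kind == "or" and not self.value > 0:
            raise ParameterError(f"odds ratio must be > 0, got {self.value}")
        if not np.isfinite(self.value):
            raise ParameterError("effect value must be finite")


@dataclass(frozen=True)
class EffectSpec:
    """Which clusters the intervention affects, how strongly and for how long.

    ``effects`` maps cluster names to :class:`Effect`; clusters absent from
    the map carry a null effect.  The effect scales annual incidence inside
    the window ``[effect_start_age, effect_start_age + effect_duration)``;
    costs and QALYs accrue from ``accrual_start_age`` to ``horizon`` and are
    discounted at ``discount_rate`` per year.
    """

    effects: Mapping[str, Effect] = field(default_factory=dict)
    effect_start_age: int = 14
    effect_duration: int = 2
    discount_rate: float = 0.03
    horizon: int = HORIZON
    accrual_start_age: int = 14

    def __post_init__(self) -> None:
        canon = {canonical_cluster(c): e for c, e in dict(self.effects).items()}
        object.__setattr__(self, "effects", canon)
        if self.effect_start_age + self.effect_duration > self.horizon:
            raise ParameterError("effect window extends beyond the horizon")
        if self.effect_duration < 0 or self.effect_start_age < 1:
            raise ParameterError("invalid effect window")
        if self.discount_rate < 0:
            raise ParameterError("discount rate must be >= 0")


@dataclass(frozen=True)
class PopulationSpec:
    """Size and composition of the simulated population."""

    n: int
    p_female: float = 0.487
    p_low_ses: float = 0.078
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ParameterError(f"population size must be > 0, got {self.n}")
        for name in ("p_female", "p_low_ses"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name}={p} outside [0, 1]")

    def stratum_weights(self) -> dict[Stratum, float]:
        """Expected population fraction per stratum (gender and SES independent)."""
        pg = {"female": self.p_female, "male": 1.0 - self.p_female}
        ps = {"low": self.p_low_ses, "medium_high": 1.0 - self.p_low_ses}
        return {st: pg[st.gender] * ps[st.ses] for st in STRATA}


# --------------------------------------------------------------------------
# Parameter bundle and file IO
# --------------------------------------------------------------------------

@dataclass
class ParameterSet:
    """A validated bundle of all model parameter tables."""

    cif: CIFTable
    gompertz: GompertzParams
    utilities: UtilityTable
    costs: CostTable

    def validate(self) -> None:
        violations = validate_cif(self.cif)
        if violations:
            v = violations[0]
            raise ParameterError(
                f"CIF table invalid ({len(violations)} violation(s)); first: "
                f"cluster={v.cluster} gender={v.gender} ses={v.ses} age={v.age} "
                f"rule={v.rule}: {v.message}"
            )


#: Canonical file names used by save_parameters / load_parameters.
PARAMETER_FILES: dict[str, str] = {
    "cif": "cif.csv",
    "gompertz": "gompertz.csv",
    "utilities": "utilities.csv",
    "costs": "costs.csv",
}


def save_parameters(params: ParameterSet, directory: str | Path) -> dict[str, Path]:
    """Write all tables of a bundle to CSV files in ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {key: directory / name for key, name in PARAMETER_FILES.items()}
    params.cif.to_csv(paths["cif"])
    params.gompertz.to_csv(paths["gompertz"])
    params.utilities.to_csv(paths["utilities"])
    params.costs.to_csv(paths["costs"])
    return paths


def load_parameters(
    paths: Mapping[str, str | Path],
    overrides: Mapping[str, float] | None = None,
) -> ParameterSet:
    """Read and validate a full parameter bundle.

    ``paths`` maps table keys (``cif``, ``gompertz``, ``utilities``,
    ``costs``) to CSV files; ``overrides`` may set scalar values, currently
    ``intervention_cost_per_student``.
    """
    overrides = dict(overrides or {})
    missing = set(PARAMETER_FILES) - set(paths)
    if missing:
        raise ParameterError(f"parameter paths missing tables: {sorted(missing)}")
    for key in PARAMETER_FILES:
        if not Path(paths[key]).exists():
            raise ParameterError(f"parameter file not found: {paths[key]}")
    cost_override = overrides.pop(
        "intervention_cost_per_student", DEFAULT_INTERVENTION_COST_PER_STUDENT
    )
    if overrides:
        raise ParameterError(f"unknown parameter overrides: {sorted(overrides)}")
    bundle = ParameterSet(
        cif=CIFTable.read_csv(paths["cif"]),
        gompertz=GompertzParams.read_csv(paths["gompertz"]),
        utilities=UtilityTable.read_csv(paths["utilities"]),
        costs=CostTable.read_csv(paths["costs"], cost_override),
    )
    bundle.validate()
    return bundle
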