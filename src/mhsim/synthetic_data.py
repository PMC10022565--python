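"""Synthetic populations, parameter bundles and event records.

The registry that parameterised the original model is not publicly
deposited, so this module generates everything the pipeline needs:

* populations with gender/SES attributes and pre-drawn uniforms,
* smooth monotone cumulative-incidence tables calibrated so that the
  population-weighted F(30) per cluster equals a stated target (by default
  the published base-case case counts divided by the population size),
* Gompertz mortality, utility and cost tables with field-realistic default
  values, and
* individual-level competing-risks event records for exercising the
  incidence estimator round trip.

Every generator is a pure function of its seed.  Synthetic incidence
curves are logistic in age (any monotone family would do; the logistic
gives controllable steepness) with a low-SES risk multiplier > 1, since
the registry population showed higher disorder prevalence in the low-SES
group.  The per-stratum split of the real curves is not published, so the
multipliers are package choices, not estimates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .des_engine import Population, sample_onset_times
from .parameters import (
    AGES,
    CLUSTERS,
    GENDERS,
    HORIZON,
    SES_LEVELS,
    STRATA,
    CIFTable,
    CostTable,
    Gompertz,
    GompertzParams,
    ParameterError,
    ParameterSet,
    PopulationSpec,
    Stratum,
    UtilityTable,
    canonical_cluster,
)
from .survival import sample_death_times

__all__ = [
    "POPULATION_TOTAL",
    "BASE_CASE_COUNTS",
    "BASE_CASE_DEATHS",
    "EventRecord",
    "default_calibration_targets",
    "gen_population",
    "gen_cif_bundle",
    "gen_event_records",
    "default_gompertz",
    "default_utilities",
    "default_costs",
    "default_parameter_set",
]

# --------------------------------------------------------------------------
# Published aggregates used as calibration targets
# --------------------------------------------------------------------------

#: Registry population aged 1-30 on the index date.
POPULATION_TOTAL: int = 609_381

#: Base-case cases per cluster over the 30-year horizon (marginal counts).
BASE_CASE_COUNTS: dict[str, int] = {
    "substance_use": 79_206,
    "anxiety": 141_397,
    "mood": 34_334,
    "psychosis_personality": 19_988,
    "conduct": 41_309,
    "adhd": 25_370,
    "eating": 9_785,
    "self_harm": 2_614,
}

#: Base-case deaths over the horizon.
BASE_CASE_DEATHS: int = 1_045


def default_calibration_targets() -> dict[str, float]:
    """Per-cluster population proportions with onset by age 30 (base case)."""
    return {c: BASE_CASE_COUNTS[c] / POPULATION_TOTAL for c in CLUSTERS}


# --------------------------------------------------------------------------
# Population generation
# --------------------------------------------------------------------------

def _open_unit(u: np.ndarray) -> np.ndarray:
    """Clip uniforms into the open interval (0, 1)."""
    return np.clip(u, 1e-16, 1.0 - 1e-16)


def gen_population(spec: PopulationSpec) -> Population:
    """Draw a population with attributes and per-individual uniforms.

    Gender and SES are independent Bernoulli draws with the spec
    probabilities; each individual receives nine uniforms (eight cluster
    onsets plus death) strictly inside (0, 1).  The master seed expands via
    ``numpy.random.SeedSequence.spawn`` into separate counter-based Philox
    streams for attributes, onsets and death, and all uniforms are drawn as
    single blocks, so the result is a pure function of the seed and does
    not depend on iteration order.
    """
    ss = np.random.SeedSequence(spec.seed)
    attr_ss, onset_ss, death_ss = ss.spawn(3)
    attr_rng = np.random.Generator(np.random.Philox(attr_ss))
    onset_rng = np.random.Generator(np.random.Philox(onset_ss))
    death_rng = np.random.Generator(np.random.Philox(death_ss))
    n = spec.n
    gender_idx = (attr_rng.random(n) >= spec.p_female).astype(np.int8)  # 0=female
    ses_idx = (attr_rng.random(n) >= spec.p_low_ses).astype(np.int8)  # 0=low
    u_onset = _open_unit(onset_rng.random((n, len(CLUSTERS))))
    u_death = _open_unit(death_rng.random(n))
    return Population(gender_idx, ses_idx, u_onset, u_death)


# --------------------------------------------------------------------------
# Calibrated cumulative-incidence bundle
# --------------------------------------------------------------------------

#: Default risk multiplier applied to low-SES strata (> 1: higher risk).
DEFAULT_LOW_SES_MULTIPLIER: float = 1.6


def _logistic_curve(ages: np.ndarray, k: float, t0: float) -> np.ndarray:
    """Monotone logistic-in-age curve normalised to 0 at age 0 and 1 at 30."""
    def sig(t):
        return 1.0 / (1.0 + np.exp(-k * (t - t0)))
    lo, hi = sig(0.0), sig(float(HORIZON))
    return (sig(ages.astype(float)) - lo) / (hi - lo)


def gen_cif_bundle(
    targets: dict[str, float] | None = None,
    shape_seed: int = 0,
    p_female: float = 0.487,
    p_low_ses: float = 0.078,
    low_ses_multiplier: float = DEFAULT_LOW_SES_MULTIPLIER,
    gender_multipliers: dict[str, float] | None = None,
) -> CIFTable:
    """Build a smooth monotone CIF table hitting per-cluster F(30) targets.

    Each cluster gets one logistic-in-age shape (steepness and midpoint
    drawn from ``shape_seed``) scaled per stratum so that the
    population-weighted F(30) equals the cluster's target exactly:

        F_{c,g,s}(t) = target_c * m_{g,s} / (sum_w w_{g,s} m_{g,s}) * L_c(t)

    with stratum weights w from the population composition and multipliers
    m (low-SES strata get ``low_ses_multiplier`` > 1; optional per-gender
    multipliers).  With all-equal multipliers every stratum shares one curve.
    """
    if targets is None:
        targets = default_calibration_targets()
    targets = {canonical_cluster(c): float(v) for c, v in targets.items()}
    missing = set(CLUSTERS) - set(targets)
    if missing:
        raise ParameterError(f"calibration targets missing clusters: {sorted(missing)}")
    for c, v in targets.items():
        if not 0.0 < v < 1.0:
            raise ParameterError(f"target for {c} must lie in (0, 1), got {v}")
    gender_multipliers = gender_multipliers or {g: 1.0 for g in GENDERS}
    weights = PopulationSpec(n=1_000, p_female=p_female, p_low_ses=p_low_ses).stratum_weights()
    mult = {
        st: gender_multipliers[st.gender] * (low_ses_multiplier if st.ses == "low" else 1.0)
        for st in STRATA
    }
    norm = sum(weights[st] * mult[st] for st in STRATA)
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(shape_seed)))
    table = CIFTable.zeros()
    for cluster in CLUSTERS:
        k = rng.uniform(0.15, 0.35)
        t0 = rng.uniform(10.0, 20.0)
        shape = _logistic_curve(AGES, k, t0)
        for st in STRATA:
            cap = targets[cluster] * mult[st] / norm
            if cap >= 1.0:
                raise ParameterError(
                    f"stratum cap {cap:.3f} >= 1 for cluster {cluster}; "
                    "reduce the multiplier or the target"
                )
            table.set_curve(cluster, st, cap * shape)
    return table


# --------------------------------------------------------------------------
# Default mortality, utility and cost tables
# --------------------------------------------------------------------------

def default_gompertz() -> GompertzParams:
    """Synthetic all-cause mortality by gender and disorder status.

    Shapes and the male/female and with/without-disorder hazard ratios are
    package choices (young-age all-cause mortality rises slowly with age;
    male mortality above female; markedly elevated hazard with a mental
    disorder).  The rate levels were calibrated once so that a base-case
    run of the default synthetic bundle at the registry population size
    yields on the order of a thousand deaths by age 30, matching the
    published base-case aggregate.
    """
    shape = 0.075
    return GompertzParams({
        ("female", "none"): Gompertz(shape=shape, rate=5.6e-6),
        ("female", "any"): Gompertz(shape=shape, rate=2.25e-5),
        ("male", "none"): Gompertz(shape=shape, rate=9.0e-6),
        ("male", "any"): Gompertz(shape=shape, rate=3.6e-5),
    })


def default_utilities() -> UtilityTable:
    """Synthetic annual utilities by gender, SES and disorder status.

    Levels follow the ordering seen in Spanish EQ-5D population norms for
    young adults: male above female, medium/high SES above low, and a
    disorder decrement of 0.12.
    """
    base = {
        ("female", "low"): 0.879,
        ("female", "medium_high"): 0.887,
        ("male", "low"): 0.883,
        ("male", "medium_high"): 0.895,
    }
    decrement = 0.12
    values: dict[tuple[str, str, str], float] = {}
    for (g, s), u in base.items():
        values[(g, s, "none")] = u
        values[(g, s, "any")] = round(u - decrement, 3)
    return UtilityTable(values)


def default_costs() -> CostTable:
    """Synthetic annual per-patient costs (€/patient-year, 2021 price level).

    Magnitudes follow the ordering reported in Spanish cost-of-brain-
    disorders studies: psychotic and self-harm clusters most expensive,
    anxiety cheapest per patient; indirect (productivity) costs dominate
    the societal excess.
    """
    rows = {
        "substance_use": (1_100.0, 500.0, 1_800.0),
        "anxiety": (700.0, 300.0, 1_100.0),
        "mood": (1_400.0, 600.0, 2_500.0),
        "psychosis_personality": (3_200.0, 1_500.0, 4_800.0),
        "conduct": (900.0, 400.0, 1_200.0),
        "adhd": (800.0, 350.0, 900.0),
        "eating": (1_900.0, 700.0, 2_100.0),
        "self_harm": (2_400.0, 900.0, 2_800.0),
    }
    frame = pd.DataFrame(
        [(c, *rows[c]) for c in CLUSTERS],
        columns=["cluster", "healthcare", "direct_non_medical", "indirect"],
    )
    return CostTable(frame)


def default_parameter_set(shape_seed: int = 0) -> ParameterSet:
    """The fully synthetic default bundle, calibrated to the published aggregates."""
    bundle = ParameterSet(
        cif=gen_cif_bundle(shape_seed=shape_seed),
        gompertz=default_gompertz(),
        utilities=default_utilities(),
        costs=default_costs(),
    )
    bundle.validate()
    return bundle


# --------------------------------------------------------------------------
# Competing-risks event records
# --------------------------------------------------------------------------

class EventRecord:
    """Schema of one event-record row (rows are carried in a DataFrame).

    Columns: ``individual_id``; ``gender``/``ses`` (the stratum);
    ``cluster`` (which cluster's competing-risks picture the row belongs
    to); ``entry_age`` (0); ``exit_age``; ``outcome`` in
    ``{"onset:<cluster>", "death", "censored"}``.  Within one cluster's
    picture the competing risks are that cluster's onset, death, and
    censoring (file closure before 30, or the administrative horizon).
    """

    COLUMNS = ("individual_id", "gender", "ses", "cluster",
               "entry_age", "exit_age", "outcome")


def gen_event_records(
    cif: CIFTable,
    gompertz: GompertzParams,
    censor_rate: float,
    n: int,
    seed: int,
    clusters: tuple[str, ...] = CLUSTERS,
    p_female: float = 0.487,
    p_low_ses: float = 0.078,
    death_hazard: bool = True,
) -> pd.DataFrame:
    """Draw individual-level competing-risks event records.

    For each individual, a latent onset age per cluster is drawn by inverse
    transform from that cluster's stratum curve, a death age from the
    no-disorder Gompertz hazard (``death_hazard=False`` suppresses death
    entirely) and an exponential censoring age with rate ``censor_rate``
    per year, truncated at the 30-year horizon.  One observation row is
    emitted per (individual, cluster): the first of {onset of that cluster,
    death, censoring} is observed.  With ``censor_rate=0`` and no deaths
    the empirical event-time CDF converges to the generating CIF.
    """
    if n < 0 or censor_rate < 0:
        raise ParameterError("n and censor_rate must be non-negative")
    if n == 0:
        return pd.DataFrame(columns=list(EventRecord.COLUMNS))
    clusters = tuple(canonical_cluster(c) for c in clusters)
    spec = PopulationSpec(n=n, p_female=p_female, p_low_ses=p_low_ses, seed=seed)
    pop = gen_population(spec)
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed).spawn(4)[3]))
    if death_hazard:
        # gender-specific death draws with no status switch (latent onsets
        # do not feed back into the fixture's mortality)
        death = np.empty(n)
        for gi, gender in enumerate(GENDERS):
            mask = pop.gender_idx == gi
            if mask.any():
                death[mask] = sample_death_times(
                    pop.u_death[mask],
                    gompertz[(gender, "none")],
                    gompertz[(gender, "none")],
                )
    else:
        death = np.full(n, np.inf)
    if censor_rate > 0:
        censor = rng.exponential(1.0 / censor_rate, size=n)
    else:
        censor = np.full(n, np.inf)
    censor = np.minimum(censor, float(HORIZON))

    frames = []
    genders = np.array(GENDERS, dtype=object)[pop.gender_idx]
    ses = np.array(SES_LEVELS, dtype=object)[pop.ses_idx]
    for cluster in clusters:
        k = CLUSTERS.index(cluster)
        onset = np.full(n, np.nan)
        for st in STRATA:
            mask = pop.stratum_mask(st)
            if mask.any():
                onset[mask] = sample_onset_times(pop.u_onset[mask, k], cif.curve(cluster, st))
        onset_t = np.where(np.isnan(onset), np.inf, onset)
        exit_age = np.minimum.reduce([onset_t, death, censor])
        outcome = np.where(
            onset_t <= exit_age, f"onset:{cluster}",
            np.where(death <= exit_age, "death", "censored"),
        )
        frames.append(pd.DataFrame({
            "individual_id": np.arange(n),
            "gender": genders,
            "ses": ses,
            "cluster": cluster,
            "entry_age": 0.0,
            "exit_age": exit_age,
            "outcome": outcome,
        }))
    return pd.concat(frames, ignore_index=True)
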