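"""QALY/cost accrual against closed forms; cost-utility classification."""

import numpy as np
import pandas as pd
import pytest

from mhsim import (
    CLUSTERS,
    Stratum,
    UtilityTable,
    accrue_costs,
    accrue_qalys,
    add_intervention_cost,
    cost_utility,
    gen_population,
    run_scenarios,
    summarize_economics,
)
from mhsim.des_engine import Trajectory
from mhsim.economics import EconResult, _classify, discounted_years
from mhsim.parameters import GENDERS, SES_LEVELS, STATUSES, PopulationSpec


def _utilities(u_none=1.0, u_any=1.0):
    return UtilityTable({
        (g, s, st): (u_none if st == "none" else u_any)
        for g in GENDERS for s in SES_LEVELS for st in STATUSES
    })


def _trajectory(onsets=None, death=None):
    onset_age = {c: None for c in CLUSTERS}
    onset_age.update(onsets or {})
    present = [v for v in onset_age.values() if v is not None]
    return Trajectory(
        onset_age=onset_age,
        first_onset_age=min(present) if present else None,
        death_age=death,
        scenario="base",
        stratum=Stratum("female", "medium_high"),
    )


class TestQalyClosedForms:
    def test_full_utility_undiscounted_window(self):
        q = accrue_qalys(_trajectory(), _utilities(), r=0.0)
        assert q == pytest.approx(16.0, abs=1e-12)

    def test_full_utility_discounted_matches_exponential_integral(self):
        q = accrue_qalys(_trajectory(), _utilities(), r=0.03)
        expected = (1.0 - np.exp(-0.03 * 16.0)) / 0.03  # = 12.71437...
        assert q == pytest.approx(expected, abs=1e-9)

    def test_onset_at_window_start_scales_by_disorder_utility(self):
        u = _utilities(u_none=0.9, u_any=0.8)
        q = accrue_qalys(_trajectory(onsets={"anxiety": 14.0}), u, r=0.0)
        assert q == pytest.approx(0.8 * 16.0, abs=1e-12)

    def test_status_switch_mid_window_splits_the_integral(self):
        u = _utilities(u_none=1.0, u_any=0.5)
        q = accrue_qalys(_trajectory(onsets={"mood": 22.0}), u, r=0.03)
        expected = (1.0 - np.exp(-0.03 * 8.0)) / 0.03 + 0.5 * (
            np.exp(-0.03 * 8.0) - np.exp(-0.03 * 16.0)
        ) / 0.03
        assert q == pytest.approx(expected, abs=1e-9)

    def test_death_truncates_accrual(self):
        q = accrue_qalys(_trajectory(death=20.0), _utilities(), r=0.0)
        assert q == pytest.approx(6.0, abs=1e-12)

    def test_discounting_never_increases_qalys(self, bundle):
        t = _trajectory(onsets={"anxiety": 16.5}, death=27.0)
        assert accrue_qalys(t, bundle.utilities, r=0.03) < accrue_qalys(
            t, bundle.utilities, r=0.0
        )

    def test_annual_step_discounting_close_to_continuous(self):
        t = _trajectory(onsets={"anxiety": 16.5})
        q_cont = accrue_qalys(_trajectory(), _utilities(), r=0.03, mode="continuous")
        q_step = accrue_qalys(_trajectory(), _utilities(), r=0.03, mode="annual")
        assert abs(q_step - q_cont) / q_cont < 0.02


class TestCostClosedForms:
    def test_no_onsets_no_costs(self, bundle):
        out = accrue_costs(_trajectory(), bundle.costs, r=0.03)
        assert all(v == 0.0 for v in out.values())

    def test_undiscounted_rectangle(self, bundle):
        # one onset at 20, €1,000/year healthcare, 10 remaining years
        costs = bundle.costs
        hc = costs.annual_cost("anxiety", "healthcare")
        out = accrue_costs(_trajectory(onsets={"anxiety": 20.0}), costs, r=0.0)
        assert out["healthcare"] == pytest.approx(hc * 10.0, abs=1e-9)

    def test_discounted_matches_exponential_integral(self, bundle):
        out = accrue_costs(_trajectory(onsets={"anxiety": 20.0}), bundle.costs, r=0.03)
        hc = bundle.costs.annual_cost("anxiety", "healthcare")
        expected = hc * (np.exp(-0.03 * 6.0) - np.exp(-0.03 * 16.0)) / 0.03
        assert out["healthcare"] == pytest.approx(expected, abs=1e-9)
        # cross-check the closed form against numeric quadrature
        from scipy.integrate import quad
        numeric, _ = quad(lambda t: hc * np.exp(-0.03 * (t - 14.0)), 20.0, 30.0)
        assert out["healthcare"] == pytest.approx(numeric, abs=1e-7)

    def test_costs_additive_across_cooccurring_clusters(self, bundle):
        both = accrue_costs(
            _trajectory(onsets={"anxiety": 20.0, "mood": 20.0}), bundle.costs, r=0.0
        )
        a = accrue_costs(_trajectory(onsets={"anxiety": 20.0}), bundle.costs, r=0.0)
        m = accrue_costs(_trajectory(onsets={"mood": 20.0}), bundle.costs, r=0.0)
        for cat in both:
            assert both[cat] == pytest.approx(a[cat] + m[cat], abs=1e-9)

    def test_onset_before_window_accrues_from_window_start(self, bundle):
        early = accrue_costs(_trajectory(onsets={"adhd": 6.0}), bundle.costs, r=0.0)
        at_start = accrue_costs(_trajectory(onsets={"adhd": 14.0}), bundle.costs, r=0.0)
        assert early == at_start

    def test_healthcare_perspective_reports_single_category(self, bundle):
        out = accrue_costs(
            _trajectory(onsets={"mood": 18.0}), bundle.costs,
            perspective="healthcare",
        )
        assert set(out) == {"healthcare"}


class TestInterventionCost:
    def test_published_total_is_exact(self):
        totals = add_intervention_cost({}, 135.70, 609_381)
        assert totals["intervention"] == pytest.approx(82_693_001.70, abs=1e-6)

    def test_zero_per_student_changes_nothing(self):
        assert add_intervention_cost({"healthcare": 5.0}, 0.0, 10)["intervention"] == 0.0

    def test_single_student(self):
        assert add_intervention_cost({}, 135.70, 1)["intervention"] == 135.70


class TestCostUtilityClassification:
    def test_cheaper_and_better_is_dominant(self):
        icur, label = _classify(-10.0, 0.01)
        assert icur is None and label == "dominant"

    def test_positive_ratio(self):
        icur, label = _classify(50.0, 0.025)
        assert icur == pytest.approx(2_000.0) and label == "icur"

    def test_dearer_and_worse_is_dominated(self):
        icur, label = _classify(5.0, -0.01)
        assert icur is None and label == "dominated"

    def test_no_difference(self):
        icur, label = _classify(0.0, 0.0)
        assert icur is None and label == "no difference"


@pytest.fixture(scope="module")
def econ_pair(bundle):
    from mhsim.effect_translation import EFFECT_PRESETS, apply_effect

    pop = gen_population(PopulationSpec(n=20_000, seed=17))
    out = apply_effect(bundle.cif, EFFECT_PRESETS["trial-5y"])
    paired = run_scenarios(pop, bundle.cif, out, bundle.gompertz)
    return summarize_economics(paired, bundle.utilities, bundle.costs, r=0.03)


class TestScenarioEconomics:
    def test_identical_scenarios_have_zero_deltas(self, bundle, small_population):
        paired = run_scenarios(small_population, bundle.cif, bundle.cif, bundle.gompertz)
        res = summarize_economics(paired, bundle.utilities, bundle.costs, r=0.03)
        res.table.loc[("intervention",), "intervention"] = 0.0  # strip programme cost
        for cua in cost_utility(res, res, "societal"):
            assert cua.delta_cost == 0.0 and cua.delta_qaly == 0.0
            assert cua.icur is None

    def test_disease_costs_never_increase_under_protection(self, econ_pair):
        t = econ_pair.table
        for cat in ("healthcare", "direct_non_medical", "indirect"):
            assert (
                t.loc[("intervention", "total"), cat]
                <= t.loc[("base", "total"), cat]
            )

    def test_qalys_never_decrease_under_protection(self, econ_pair):
        t = econ_pair.table
        assert t.loc[("intervention", "total"), "qaly"] >= t.loc[("base", "total"), "qaly"]

    def test_societal_delta_is_category_sum(self, econ_pair):
        hc = cost_utility(econ_pair, econ_pair, "healthcare")
        so = cost_utility(econ_pair, econ_pair, "societal")
        t = econ_pair.table
        for h, s in zip(hc, so):
            parts = sum(
                t.loc[("intervention", h.subgroup), cat]
                - t.loc[("base", h.subgroup), cat]
                for cat in ("healthcare", "direct_non_medical", "indirect")
            ) + t.loc[("intervention", h.subgroup), "intervention"]
            assert s.delta_cost == pytest.approx(parts, abs=1e-9)

    def test_subgroups_cover_total_and_four_strata(self, econ_pair):
        subgroups = set(econ_pair.table.loc["base"].index)
        assert subgroups == {
            "total", "female/low", "female/medium_high", "male/low", "male/medium_high",
        }


class TestVectorisedAgreesWithScalar:
    def test_vector_and_scalar_accruals_match(self, bundle, small_population):
        paired = run_scenarios(small_population, bundle.cif, bundle.cif, bundle.gompertz)
        res = summarize_economics(paired, bundle.utilities, bundle.costs, r=0.03)
        # recompute the base-scenario totals trajectory by trajectory
        qalys, hc = [], []
        for i in range(300):
            profile = small_population[i]
            traj = paired.base.trajectory(i, profile.stratum)
            qalys.append(accrue_qalys(traj, bundle.utilities, r=0.03))
            hc.append(accrue_costs(traj, bundle.costs, r=0.03)["healthcare"])
        from mhsim.economics import _vector_costs, _vector_qalys

        vq = _vector_qalys(
            paired.base, small_population.gender_idx, small_population.ses_idx,
            bundle.utilities, 0.03, (14.0, 30.0), "continuous",
        )[:300]
        vc = _vector_costs(paired.base, bundle.costs, 0.03, (14.0, 30.0), "continuous")
        assert np.allclose(vq, qalys, atol=1e-9)
        assert np.allclose(vc["healthcare"][:300], hc, atol=1e-9)
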