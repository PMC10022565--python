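"""Effect conversions (OR/SMD/RR) and intervention-curve construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import logistic

from mhsim import (
    AGES,
    CLUSTERS,
    STRATA,
    CIFTable,
    Effect,
    EffectSpec,
    annual_to_cif,
    apply_effect,
    cif_to_annual,
    or_to_rr,
    smd_to_or,
)
from mhsim.effect_translation import EFFECT_PRESETS


class TestCifAnnualDecomposition:
    def test_constant_hazard_curve(self):
        f = annual_to_cif(np.full(30, 0.1))
        assert f[0] == pytest.approx(0.1)
        assert f[1] == pytest.approx(0.19)
        q = cif_to_annual(f)
        assert np.allclose(q, 0.1, atol=1e-14)

    def test_flat_year_gives_zero_incidence(self):
        f = np.array([0.1] * 30)
        q = cif_to_annual(f)
        assert q[0] == pytest.approx(0.1)
        assert np.all(q[1:] == 0.0)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.0, 0.3), min_size=30, max_size=30))
    def test_round_trip_is_identity(self, qs):
        q = np.array(qs)
        f = annual_to_cif(q)
        assert np.allclose(annual_to_cif(cif_to_annual(f)), f, atol=1e-12)

    def test_bundle_curves_round_trip(self, bundle):
        for cluster in CLUSTERS:
            for stn in STRATA:
                f = np.asarray(bundle.cif.curve(cluster, stn))
                assert np.allclose(annual_to_cif(cif_to_annual(f)), f, atol=1e-12)


class TestOrToRr:
    def test_small_baseline_limit_returns_or(self):
        assert or_to_rr(0.71, 1e-12) == pytest.approx(0.71, abs=1e-9)

    def test_null_or_gives_null_rr(self):
        for p0 in (0.0, 0.2, 0.9):
            assert or_to_rr(1.0, p0) == pytest.approx(1.0)

    def test_worked_example(self):
        assert or_to_rr(0.66, 0.5) == pytest.approx(0.66 / 0.83, abs=1e-10)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        or_value=st.floats(0.05, 20.0),
        p0=st.floats(0.001, 0.95),
    )
    def test_agrees_with_two_by_two_table_oracle(self, or_value, p0):
        """Brute force: construct the exposed-arm risk from the odds."""
        odds1 = or_value * p0 / (1.0 - p0)
        p1 = odds1 / (1.0 + odds1)
        assert or_to_rr(or_value, p0) == pytest.approx(p1 / p0, rel=1e-12)

    def test_degenerate_baseline_rejected(self):
        with pytest.raises(Exception):
            or_to_rr(0.7, 1.0)


class TestSmdToOr:
    def test_null_smd(self):
        assert smd_to_or(0.0) == 1.0

    @pytest.mark.parametrize("smd", [-0.18, -0.13, 0.3])
    def test_matches_logistic_shift_oracle(self, smd):
        """Independent oracle: odds ratio of exceeding a threshold between
        two logistic distributions shifted by smd standard deviations."""
        scale = 1.0  # logistic scale; sd = scale*pi/sqrt(3)
        sd = scale * np.pi / np.sqrt(3.0)
        threshold = 0.37  # arbitrary; the logistic OR is threshold-free
        p_ctrl = logistic.sf(threshold, loc=0.0, scale=scale)
        p_trt = logistic.sf(threshold, loc=smd * sd, scale=scale)
        oracle = (p_trt / (1 - p_trt)) / (p_ctrl / (1 - p_ctrl))
        assert smd_to_or(smd) == pytest.approx(oracle, rel=1e-10)

    def test_known_values(self):
        assert smd_to_or(-0.18) == pytest.approx(0.72145, abs=1e-4)
        assert smd_to_or(-0.13) == pytest.approx(0.78995, abs=1e-4)


class TestApplyEffect:
    def test_null_or_leaves_table_unchanged(self, bundle):
        spec = EffectSpec(effects={"anxiety": Effect("or", 1.0)})
        out = apply_effect(bundle.cif, spec)
        assert np.allclose(out.values, bundle.cif.values, atol=1e-12)

    def test_vanishing_or_flattens_curve_from_window_start(self, bundle):
        spec = EffectSpec(
            effects={"anxiety": Effect("or", 1e-12)},
            effect_start_age=14, effect_duration=16,
        )
        out = apply_effect(bundle.cif, spec)
        for stn in STRATA:
            f = np.asarray(out.curve("anxiety", stn))
            base = np.asarray(bundle.cif.curve("anxiety", stn))
            # flat across the window ages 14..29; age 30 lies outside the
            # window (start + duration <= horizon) and resumes baseline q
            assert np.allclose(f[13:29], f[13], atol=1e-9)
            assert np.allclose(f[:13], base[:13], atol=1e-12)
            assert f[29] < base[29]

    def test_constant_hazard_direct_product_oracle(self):
        """q = 0.01 everywhere, OR 0.71 in a 2-year window from age 14:
        F'(30) = 1 - 0.99^28 * (1 - rr*0.01)^2 with rr the Zhang-Yu
        conversion at p0 = 0.01."""
        table = CIFTable.zeros()
        f = annual_to_cif(np.full(30, 0.01))
        for c in CLUSTERS:
            for stn in STRATA:
                table.set_curve(c, stn, f)
        spec = EffectSpec(effects={"anxiety": Effect("or", 0.71)},
                          effect_start_age=14, effect_duration=2)
        out = apply_effect(table, spec)
        rr = or_to_rr(0.71, 0.01)
        expected = 1.0 - (0.99 ** 28) * (1.0 - rr * 0.01) ** 2
        got = out.curve("anxiety", STRATA[0])[-1]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_protective_effect_dominance(self, bundle):
        """rr <= 1: F' <= F from the window start, equality before it."""
        for preset in ("trial-2y", "trial-5y", "meta-1y"):
            spec = EFFECT_PRESETS[preset]
            out = apply_effect(bundle.cif, spec)
            s = spec.effect_start_age
            for cluster in spec.effects:
                for stn in STRATA:
                    base = np.asarray(bundle.cif.curve(cluster, stn))
                    new = np.asarray(out.curve(cluster, stn))
                    assert np.allclose(new[: s - 1], base[: s - 1], atol=1e-12)
                    assert np.all(new[s - 1:] <= base[s - 1:] + 1e-12)

    def test_unaffected_clusters_bitwise_unchanged(self, bundle):
        out = apply_effect(bundle.cif, EFFECT_PRESETS["trial-2y"])
        for cluster in CLUSTERS:
            if cluster in ("anxiety", "mood"):
                continue
            for stn in STRATA:
                assert np.array_equal(
                    out.curve(cluster, stn), bundle.cif.curve(cluster, stn)
                )

    def test_longer_window_averts_at_least_as_much(self, bundle):
        f2 = apply_effect(bundle.cif, EFFECT_PRESETS["trial-2y"])
        f5 = apply_effect(bundle.cif, EFFECT_PRESETS["trial-5y"])
        for cluster in ("anxiety", "mood"):
            for stn in STRATA:
                assert np.all(
                    np.asarray(f5.curve(cluster, stn))
                    <= np.asarray(f2.curve(cluster, stn)) + 1e-12
                )

    def test_cumulative_mode_also_dominates(self, bundle):
        out = apply_effect(bundle.cif, EFFECT_PRESETS["trial-2y"], mode="cumulative")
        for stn in STRATA:
            base = np.asarray(bundle.cif.curve("anxiety", stn))
            new = np.asarray(out.curve("anxiety", stn))
            assert np.all(new <= base + 1e-12)
            assert np.allclose(new[:13], base[:13], atol=1e-12)
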