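import numpy as np
import pytest

from pocketscreen.assay_analysis import (
    CurveStats,
    EC50Estimate,
    PhenotypeCounts,
    PolymerizationCurve,
    curve_stats,
    death_ec50,
    fold_changes,
    growth_ec50,
    normalize_polymerization,
    phenotype_score,
    polymer_state_proportions,
)
from pocketscreen.synthetic_data import gen_cell_series, gen_polymerization


def curve(condition, times, readings):
    return PolymerizationCurve(condition, np.asarray(times, float), np.asarray(readings, float))


class TestNormalization:
    def test_reference_final_maps_to_100(self):
        c = curve("TAX", [0, 10, 20, 30], [0.0, 3.0, 8.0, 10.0])
        norm = normalize_polymerization([c], "TAX")["TAX"]
        assert norm.readings[-1] == pytest.approx(100.0)
        assert norm.readings[0] == pytest.approx(0.0)

    def test_constant_curve_at_minimum_maps_to_zero(self):
        ref = curve("TAX", [0, 15, 30], [1.0, 5.0, 9.0])
        flat = curve("FLAT", [0, 15, 30], [1.0, 1.0, 1.0])
        norm = normalize_polymerization([ref, flat], "TAX")
        assert np.allclose(norm["FLAT"].readings, 0.0)

    def test_closed_form_affine_transform(self):
        curves, _ = gen_polymerization(noise_sd=0.0, seed=4)
        norm = normalize_polymerization(curves, "TAX")
        f_min = min(c.readings.min() for c in curves)
        ref_end = next(c for c in curves if c.condition == "TAX").readings[-1]
        for c in curves:
            expected = 100.0 * (c.readings - f_min) / (ref_end - f_min)
            np.testing.assert_allclose(norm[c.condition].readings, expected, atol=1e-9)

    def test_gain_offset_invariance(self):
        """Affine rescaling of the raw AU readings cancels in normalization."""
        curves, _ = gen_polymerization(noise_sd=0.0, seed=5)
        rescaled = [
            PolymerizationCurve(c.condition, c.times, 7.0 + 3.5 * c.readings)
            for c in curves
        ]
        a = normalize_polymerization(curves, "TAX")
        b = normalize_polymerization(rescaled, "TAX")
        for cond in a:
            np.testing.assert_allclose(a[cond].readings, b[cond].readings, atol=1e-9)
            sa, sb = curve_stats(a[cond]), curve_stats(b[cond])
            assert sa.vmax == pytest.approx(sb.vmax)
            assert sa.mep == pytest.approx(sb.mep)

    def test_degenerate_reference_rejected(self):
        flat = curve("TAX", [0, 30], [2.0, 2.0])
        with pytest.raises(ValueError, match="degenerate"):
            normalize_polymerization([flat], "TAX")

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            normalize_polymerization([curve("A", [0, 30], [0, 1])], "TAX")


class TestCurveStats:
    def test_straight_line(self):
        times = np.arange(0, 31, 1.0)
        st = curve_stats(curve("x", times, times))  # 1 %/min up to 30%
        assert st.vmax == pytest.approx(1.0)
        assert st.mep == pytest.approx(30.0)

    def test_flat_curve(self):
        st = curve_stats(curve("x", [0, 10, 20, 30], [20.0] * 4))
        assert st.vmax == pytest.approx(0.0)
        assert st.mep == pytest.approx(20.0)

    def test_logistic_max_slope_recovered(self):
        curves, truth = gen_polymerization(v_true=2.8, plateau=34.5, noise_sd=0.0, seed=0)
        norm = normalize_polymerization(curves, "TAX")
        for cond in ("TAX", "DMSO", "TEST"):
            st = curve_stats(norm[cond])
            assert st.vmax == pytest.approx(truth["vmax"][cond], rel=0.05)
            assert st.mep == pytest.approx(truth["mep"][cond], rel=1e-6)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least"):
            curve_stats(curve("x", [0, 1], [0, 1]))


class TestFoldChanges:
    def _stats(self, vmax, mep):
        return CurveStats(condition="x", vmax=vmax, mep=mep)

    def test_raloxifene_like_mep_ratio(self):
        fc = fold_changes(self._stats(2.8, 34.5), self._stats(1.0, 20.5))
        assert round(fc.fc_mep, 1) == 1.7

    def test_tamoxifen_like_suppression(self):
        fc = fold_changes(self._stats(0.4, 10.2), self._stats(1.0, 20.5))
        assert round(fc.fc_mep, 1) == 0.5
        assert fc.classification == "suppressor"

    def test_vehicle_against_itself_is_exactly_one(self):
        dmso = self._stats(1.0, 20.5)
        fc = fold_changes(dmso, dmso)
        assert fc.fc_vmax == 1.0
        assert fc.fc_mep == 1.0

    def test_enhancer_classification(self):
        fc = fold_changes(self._stats(2.0, 40.0), self._stats(1.0, 20.0))
        assert fc.classification == "enhancer"

    def test_mixed_classification(self):
        fc = fold_changes(self._stats(2.0, 10.0), self._stats(1.0, 20.0))
        assert fc.classification == "mixed"

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fold_changes(self._stats(1, 1), self._stats(0.0, 20.0))


class TestPhenotypeScore:
    def test_no_abnormalities(self):
        pc = PhenotypeCounts("DMSO", {"bundling": 0, "rings": 0}, n_cells=100)
        assert phenotype_score(pc) == 0.0

    def test_multiple_categories_sum(self):
        pc = PhenotypeCounts(
            "RAL",
            {"bundling": 10, "abnormal_org": 5, "abnormal_spindle": 3, "rings": 2},
            n_cells=20,
        )
        assert phenotype_score(pc) == pytest.approx(1.0)

    def test_single_cell(self):
        assert phenotype_score(PhenotypeCounts("x", {"bundling": 1}, 1)) == 1.0

    def test_linear_and_scale_invariant(self):
        base = {"a": 3, "b": 7}
        s1 = phenotype_score(PhenotypeCounts("x", base, 40))
        s2 = phenotype_score(PhenotypeCounts("x", {k: 5 * v for k, v in base.items()}, 200))
        assert s1 == pytest.approx(s2)

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            PhenotypeCounts("x", {"a": 1}, 0)


class TestPolymerStateProportions:
    @pytest.mark.parametrize(
        "n_poly,n_total,expected", [(50, 100, (0.5, 0.5)), (0, 10, (0.0, 1.0))]
    )
    def test_fractions(self, n_poly, n_total, expected):
        assert polymer_state_proportions(n_poly, n_total) == pytest.approx(expected)

    def test_binomial_draw_within_bounds(self):
        # 627 cells, planted polymerized rate 0.3 (vehicle-scale cell count)
        rng = np.random.default_rng(5)
        n_total, rate = 627, 0.3
        n_poly = int(rng.binomial(n_total, rate))
        p, s = polymer_state_proportions(n_poly, n_total)
        half_width = 1.96 * np.sqrt(rate * (1 - rate) / n_total)
        assert abs(p - rate) < half_width
        assert p + s == pytest.approx(1.0)

    def test_bounds_violation(self):
        with pytest.raises(ValueError):
            polymer_state_proportions(11, 10)


class TestGrowthEC50:
    def _series(self, slopes, t_max=48.0, n=13):
        times = np.linspace(0, t_max, n)
        return {c: (times, 10 + s * times) for c, s in slopes.items()}

    def test_hand_interpolation_in_log_space(self):
        v = 2.0
        vehicle = (np.linspace(0, 48, 13), 10 + v * np.linspace(0, 48, 13))
        series = self._series({10.0: 0.9 * v, 100.0: 0.1 * v})
        est = growth_ec50(series, vehicle)
        assert est.value == pytest.approx(10 ** 1.5, rel=1e-9)  # 31.6 µM

    def test_no_bracket_not_assigned(self):
        v = 2.0
        vehicle = (np.linspace(0, 48, 13), 10 + v * np.linspace(0, 48, 13))
        series = self._series({10.0: 0.9 * v, 100.0: 0.8 * v})
        est = growth_ec50(series, vehicle)
        assert not est.assigned
        assert "bracket" in est.reason

    def test_non_positive_vehicle_not_assigned(self):
        times = np.linspace(0, 48, 13)
        vehicle = (times, 10 - 0.1 * times)
        est = growth_ec50(self._series({1.0: 0.5, 10.0: 0.1}), vehicle)
        assert not est.assigned

    def test_unit_relabeling_equivariance(self):
        """Converting µM to nM multiplies the estimate by the same factor."""
        growth, _, vehicle, _ = gen_cell_series(noise_sd=0.0, seed=3)
        est_um = growth_ec50(growth, vehicle)
        est_nm = growth_ec50({1e3 * c: v for c, v in growth.items()}, vehicle)
        assert est_nm.value == pytest.approx(1e3 * est_um.value, rel=1e-9)

    def test_recovery_noiseless(self):
        growth, _, vehicle, truth = gen_cell_series(ec50_true=25.0, noise_sd=0.0, seed=0)
        est = growth_ec50(growth, vehicle)
        assert est.value == pytest.approx(truth["ec50_p"], rel=0.10)


class TestDeathEC50:
    def test_exact_4pl_recovered(self):
        doses = np.logspace(0, 2.5, 8)
        y = 1.0 / (1.0 + (50.0 / doses) ** 1.0)
        est = death_ec50(doses, y)
        assert est.value == pytest.approx(50.0, rel=1e-6)

    def test_flat_data_not_assigned(self):
        doses = np.logspace(0, 2, 6)
        est = death_ec50(doses, np.full(6, 0.2))
        assert not est.assigned
        assert "span" in est.reason

    def test_too_few_doses_not_assigned(self):
        est = death_ec50([1.0, 10.0, 100.0], [0.1, 0.5, 0.9])
        assert not est.assigned
        assert "4" in est.reason

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            death_ec50([1, 2, 3, 4], [0.1, 0.5, 1.2, 0.9])

    def test_noisy_recovery_median_within_20pct(self):
        errors = []
        for seed in range(20):
            _, death_a, _, truth = gen_cell_series(death_noise_sd=0.05, seed=seed)
            _, death_b, _, _ = gen_cell_series(death_noise_sd=0.05, seed=seed + 10_000)
            concs = np.concatenate([death_a["24"][0], death_b["24"][0]])
            fracs = np.concatenate([death_a["24"][1], death_b["24"][1]])
            est = death_ec50(concs, fracs)
            assert est.assigned
            errors.append(abs(est.value - truth["ec50_d24"]) / truth["ec50_d24"])
        assert np.median(errors) < 0.20
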