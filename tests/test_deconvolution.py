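"""Linear-system construction, PSO solving, background correction, evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import lsq_linear

from mctamap.deconvolution import (
    DEFAULT_TISSUES,
    PSOConfig,
    WBCBackgroundModel,
    absolute_ge,
    build_system,
    correct_background,
    deconvolve,
    estimate_detection_limit,
    evaluate_recovery,
    pso_solve,
)
from mctamap.markers import select_tissue_markers


@pytest.fixture(scope="module")
def system(small_bundle):
    ms = select_tissue_markers(small_bundle.panel, small_bundle.wbc_training,
                               small_bundle.marker_info["distance_bp"])
    return small_bundle, ms


class TestBuildSystem:
    def test_shapes(self, system):
        bundle, ms = system
        plasma = bundle.panel["liver"] * 0.0
        mt, mp = build_system(ms, bundle.panel, plasma)
        assert mt.shape == (8, 8)
        assert len(mp) == 8

    def test_pure_wbc_gives_zero_mp(self, system):
        bundle, ms = system
        plasma = pd.Series(0.0, index=bundle.panel.index)
        _, mp = build_system(ms, bundle.panel, plasma)
        assert (mp == 0).all()

    def test_linear_construction(self, system):
        # plasma built as an exact 2% liver mixture: MP = 0.02 * MT[:, liver]
        bundle, ms = system
        plasma = 0.02 * bundle.panel["liver"]
        mt, mp = build_system(ms, bundle.panel, plasma)
        np.testing.assert_allclose(mp.to_numpy(), 0.02 * mt["liver"].to_numpy())

    def test_empty_tissue_dropped_with_warning(self, system):
        bundle, ms = system
        ms2 = ms.subset([m for m in ms.markers
                         if ms.table.loc[m, "source_tissue"] != "skin"])
        with pytest.warns(UserWarning, match="skin"):
            mt, mp = build_system(ms2, bundle.panel, bundle.panel["liver"] * 0)
        assert list(mt.index) == [t for t in DEFAULT_TISSUES if t != "skin"]


class TestPsoSolve:
    def random_system(self, rng):
        diag = rng.uniform(500, 4000, size=8)
        mt = np.diag(diag) + rng.uniform(0, 1, size=(8, 8))
        return mt

    def test_zero_rhs_zero_solution(self, rng):
        mt = self.random_system(rng)
        p, runs, resid = pso_solve(mt, np.zeros(8), PSOConfig(seed=0))
        assert np.max(np.abs(p)) < 1e-4

    def test_noiseless_recovery_vs_oracle(self, rng):
        mt = self.random_system(rng)
        p_true = np.array([0.05, 0, 0.01, 0, 0, 0.002, 0, 0])
        mp = mt @ p_true
        p, _, resid = pso_solve(mt, mp, PSOConfig(seed=1))
        oracle = lsq_linear(mt, mp, bounds=(0, 1)).x
        assert np.max(np.abs(p - p_true)) < 2e-3
        assert np.max(np.abs(p - oracle)) < 2e-3

    def test_single_tissue_spike(self, system):
        bundle, ms = system
        plasma = 0.02 * bundle.panel["liver"]
        mt, mp = build_system(ms, bundle.panel, plasma)
        p, _, _ = pso_solve(mt, mp, PSOConfig(seed=2))
        assert p["liver"] == pytest.approx(0.02, abs=1e-3)
        assert (p.drop("liver") < 1e-3).all()

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="finite"):
            pso_solve(np.full((2, 2), np.nan), np.zeros(2))

    def test_median_reduces_spread(self, rng):
        """The median of 10 runs varies less across seeds than single runs do."""
        mt = self.random_system(rng)
        mp = mt @ np.array([0.01, 0, 0, 0.003, 0, 0, 0, 0]) + rng.normal(0, 0.5, 8)
        medians, singles = [], []
        for seed in range(6):
            cfg = PSOConfig(seed=seed, iterations=150, stall_restart=0)
            med, runs, _ = pso_solve(mt, mp, cfg)
            medians.append(med)
            singles.extend(np.asarray(runs))
        med_std = np.vstack(medians).std(axis=0).mean()
        single_std = np.vstack(singles).std(axis=0).mean()
        assert med_std <= single_std


class TestBackgroundCorrection:
    def series(self, **kv):
        s = pd.Series(0.0, index=list(DEFAULT_TISSUES))
        for k, v in kv.items():
            s[k] = v
        return s

    def test_liver_above_threshold_subtracted(self):
        out = correct_background(self.series(liver=0.013))
        assert out["liver"] == pytest.approx(0.013 - 0.00015)

    def test_stomach_below_threshold_zeroed(self):
        out = correct_background(self.series(stomach=0.015))
        assert out["stomach"] == 0.0

    def test_all_zero_passthrough(self):
        out = correct_background(self.series())
        assert (out == 0).all()

    def test_idempotent_with_zero_model(self):
        zero = WBCBackgroundModel(means=(0.0,) * 8, thresholds=(0.0,) * 8)
        once = correct_background(self.series(liver=0.013))
        twice = correct_background(once, zero)
        pd.testing.assert_series_equal(once, twice, check_names=False)

    def test_model_invariants_enforced(self):
        with pytest.raises(ValueError, match="mean"):
            WBCBackgroundModel(means=(0.5,) * 8, thresholds=(0.1,) * 8)

    def test_calibration_from_wbc_runs(self, rng):
        fr = pd.DataFrame(rng.uniform(0, 0.001, (14, 8)),
                          columns=list(DEFAULT_TISSUES))
        model = WBCBackgroundModel.from_wbc_fractions(fr)
        frame = model.as_frame()
        assert (frame["threshold"] >= frame["mean"]).all()
        assert frame.loc["liver", "mean"] == pytest.approx(fr["liver"].mean())


class TestAbsoluteGe:
    def test_zero_fraction(self):
        s = pd.Series({"liver": 0.0})
        assert absolute_ge(s, 6.5)["liver"] == 0.0

    def test_derived_example(self):
        # 6.5 ng/mL at 3.3 pg per haploid genome and a 1.3% fraction
        s = pd.Series({"liver": 0.013})
        assert absolute_ge(s, 6.5)["liver"] == pytest.approx(25.6, abs=0.05)

    def test_linear_in_concentration(self):
        s = pd.Series({"liver": 0.013, "lung": 0.001})
        pd.testing.assert_series_equal(absolute_ge(s, 13.0), 2 * absolute_ge(s, 6.5))

    def test_rejects_bad_constant(self):
        with pytest.raises(ValueError):
            absolute_ge(pd.Series({"liver": 0.01}), 6.5, pg_per_haploid_ge=0)


class TestEvaluation:
    def test_identity_fit(self):
        slope, intercept, r2 = evaluate_recovery([0.01, 0.02, 0.04], [0.01, 0.02, 0.04])
        assert (slope, intercept, r2) == pytest.approx((1.0, 0.0, 1.0))

    def test_hand_ols(self):
        slope, intercept, r2 = evaluate_recovery([0, 1, 2], [0, 2, 4])
        assert (slope, intercept, r2) == pytest.approx((2.0, 0.0, 1.0))

    def test_constant_truth_signalled(self):
        with pytest.raises(ValueError, match="distinct"):
            evaluate_recovery([0.01, 0.01, 0.01], [1, 2, 3])

    def test_detection_limit_planted(self):
        series = {0.0025: [0.24e-2 + d for d in (-0.02e-2, 0, 0.01e-2, 0.02e-2)],
                  0.005: [0.5e-2, 0.49e-2, 0.51e-2, 0.5e-2]}
        null = [0.0, 0.01e-2, 0.0, 0.005e-2]
        limit, table = estimate_detection_limit(series, null)
        assert limit == 0.0025
        assert table["detected"].all()

    def test_identical_distributions_not_detected(self):
        series = {0.01: [0.0, 0.0, 0.0]}
        limit, table = estimate_detection_limit(series, [0.0, 0.0, 0.0])
        assert limit is None
        assert table.loc[0, "p_value"] == 1.0

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            estimate_detection_limit({0.01: [0.01]}, [0.0, 0.0])

    def test_power_monotone_in_replicates(self, rng):
        """With a fixed small effect, more replicates never raise the limit."""
        grid = [0.001, 0.002, 0.004, 0.008]
        limits = {}
        for n in (4, 16):
            series = {f: rng.normal(f, 0.0025, n) for f in grid}
            null = rng.normal(0, 0.0025, n)
            lim, _ = estimate_detection_limit(series, null)
            limits[n] = lim if lim is not None else np.inf
        assert limits[16] <= limits[4]


def test_deconvolve_end_to_end_two_tissue(system):
    """Noiseless two-tissue plasma (liver 4% + pancreas 2%) is recovered
    within 0.5 percentage points by the full deconvolution path."""
    bundle, ms = system
    plasma = 0.04 * bundle.panel["liver"] + 0.02 * bundle.panel["pancreas"]
    res = deconvolve(ms, bundle.panel, plasma, pso=PSOConfig(seed=3),
                     background=None)
    assert res.raw_fractions["liver"] == pytest.approx(0.04, abs=0.005)
    assert res.raw_fractions["pancreas"] == pytest.approx(0.02, abs=0.005)
    assert res.per_run.shape == (10, 8)
    assert ((res.raw_fractions >= 0) & (res.raw_fractions <= 1)).all()
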