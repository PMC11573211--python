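"""Normalisation ladder: worked examples, fixed points, planted-factor recovery."""

import numpy as np
import pytest

from sfsomaqc.qc_metrics import percent_cv_table
from sfsomaqc.standardise import (
    StandardisationError,
    calibrate,
    dilution_adjusted_abundance,
    exp_transform,
    hybridisation_normalise,
    log_transform,
    median_normalise,
    plate_scale,
    run_standardisation,
)

from conftest import make_dataset


class TestHybridisation:
    def test_three_well_toy_matches_hand_evaluation(self):
        # controls per well: (100,100,100), (50,50,50), (200,200,200)
        # references are the medians (100,100,100) -> factors (1, 2, 0.5)
        rfu = np.array([[100, 100, 100, 1000.0],
                        [50, 50, 50, 600.0],
                        [200, 200, 200, 800.0]])
        ds = make_dataset(rfu, hyb=3)
        out, factors = hybridisation_normalise(ds)
        np.testing.assert_allclose(factors.to_numpy(), [1.0, 2.0, 0.5])
        np.testing.assert_allclose(out.values[:, 3], [1000.0, 1200.0, 400.0])

    def test_identity_when_all_wells_at_reference(self):
        rfu = np.tile([100.0, 120.0, 90.0, 500.0], (4, 1))
        ds = make_dataset(rfu, hyb=3)
        out, factors = hybridisation_normalise(ds)
        np.testing.assert_allclose(factors.to_numpy(), 1.0)
        np.testing.assert_allclose(out.values, rfu)

    def test_post_normalisation_median_ratio_is_one(self, clean4):
        """Per-well median of (reference / RFU) equals 1 after the step."""
        _, dataset, _ = clean4
        hyb = dataset.somamers["is_hyb_control"].fillna(False).astype(bool).to_numpy()
        plate = dataset.samples["plate_id"].astype(str).to_numpy()
        out, _ = hybridisation_normalise(dataset)
        for q in np.unique(plate):
            rows = plate == q
            ref = np.median(dataset.values[rows][:, hyb], axis=0)
            per_well_median = np.median(ref[None, :] / out.values[rows][:, hyb],
                                        axis=1)
            np.testing.assert_allclose(per_well_median, 1.0, atol=1e-9)

    def test_idempotent_on_multiplicative_data(self):
        rng = np.random.default_rng(0)
        well = np.exp(rng.normal(0, 0.3, 12))
        ctrl = np.array([100.0, 150.0, 80.0])
        base = rng.lognormal(7, 0.5, 20)
        rfu = well[:, None] * np.concatenate([ctrl, base])[None, :]
        ds = make_dataset(rfu, hyb=3)
        once, _ = hybridisation_normalise(ds)
        once.scale_state = "raw"
        twice, f2 = hybridisation_normalise(once)
        np.testing.assert_allclose(f2.to_numpy(), 1.0, atol=1e-12)
        np.testing.assert_allclose(twice.values, once.values, rtol=1e-12)

    def test_errors(self):
        ds = make_dataset(np.full((3, 4), 100.0), hyb=0)
        with pytest.raises(StandardisationError, match="no hybridisation"):
            hybridisation_normalise(ds)
        bad = make_dataset(np.full((3, 4), 100.0), hyb=2)
        bad.rfu.iloc[1, 0] = 0.0
        with pytest.raises(StandardisationError, match="well"):
            hybridisation_normalise(bad)


class TestPlateScale:
    def _two_plate(self, bright=1.0):
        rng = np.random.default_rng(1)
        base = rng.lognormal(7, 0.3, 6)
        rows, roles, plates = [], [], []
        for q, mult in (("P1", 1.0), ("P2", bright)):
            for r in range(3):
                rows.append(base * mult)
                roles.append("calibrator")
                plates.append(q)
            rows.append(base * mult * 1.1)
            roles.append("study")
            plates.append(q)
        ds = make_dataset(np.array(rows), roles=roles, plates=plates,
                          calibrator_reference=base)
        return ds, base

    def test_reference_plates_untouched(self):
        ds, _ = self._two_plate(1.0)
        _, factors = plate_scale(ds)
        np.testing.assert_allclose(factors.to_numpy(), 1.0, rtol=1e-12)

    def test_brighter_plate_scaled_down(self):
        ds, _ = self._two_plate(1.5)
        _, factors = plate_scale(ds)
        np.testing.assert_allclose(factors["P2"], 2.0 / 3.0, rtol=1e-12)

    def test_planted_plate_factors_recovered(self, clean4):
        # hybridisation normalisation re-centres each plate at its median
        # well factor, so that offset becomes part of the plate-level truth
        _, dataset, truth = clean4
        hyb_out, _ = hybridisation_normalise(dataset)
        _, factors = plate_scale(hyb_out)
        wmed = truth.well_log_factor.groupby(level="plate_id")["log_factor"].median()
        expected = np.exp(-(truth.plate_log_factor + wmed))
        ratio = (factors / expected.loc[factors.index]).to_numpy()
        assert np.all(np.abs(ratio - 1.0) < 0.02)

    def test_plate_without_calibrators_rejected(self):
        ds = make_dataset(np.full((4, 5), 100.0), roles=["study"] * 4)
        with pytest.raises(StandardisationError, match="calibrator"):
            plate_scale(ds)


class TestCalibrate:
    def test_half_reference_gives_factor_two(self):
        base = np.array([100.0, 200.0, 400.0])
        rfu = np.vstack([base * 2, base * 2, base * 2, base * 5])
        ds = make_dataset(rfu, roles=["calibrator"] * 3 + ["study"],
                          calibrator_reference=base)
        out, factors = calibrate(ds)
        np.testing.assert_allclose(factors.loc["P1"].to_numpy(), 0.5)
        np.testing.assert_allclose(out.values[3], base * 2.5)

    def test_calibrator_medians_pinned_to_reference(self, clean4):
        _, dataset, _ = clean4
        out, _ = calibrate(dataset)
        refs = out.somamers["calibrator_reference"].to_numpy()
        prot = out.protein_mask()
        cal = out.role_mask("calibrator")
        plate = out.samples["plate_id"].astype(str).to_numpy()
        for q in np.unique(plate):
            med = np.median(out.values[cal & (plate == q)], axis=0)
            np.testing.assert_allclose(med[prot], refs[prot], rtol=1e-9)


class TestMedianNormalise:
    def test_uniformly_bright_sample_restored(self):
        rng = np.random.default_rng(2)
        base = rng.lognormal(7, 0.4, 10)
        rfu = np.vstack([base, base, base * 3.0])
        ds = make_dataset(rfu)
        out, factors = median_normalise(ds)
        np.testing.assert_allclose(factors.iloc[2, 0], 1.0 / 3.0, rtol=1e-12)
        np.testing.assert_allclose(out.values[2], base, rtol=1e-12)

    def test_identical_samples_all_factors_one(self):
        rfu = np.tile(np.linspace(100, 1000, 8), (5, 1))
        _, factors = median_normalise(make_dataset(rfu))
        np.testing.assert_allclose(factors.to_numpy(), 1.0)

    def test_true_signal_agreement_decreases(self, clean4):
        """Median normalisation divides out genuine per-sample biology."""
        _, dataset, truth = clean4

        def agreement(ds):
            m = ds.study_mask()
            prot = ds.protein_mask()
            x = np.log(ds.values[m][:, prot])
            t = truth.true_log_biological.to_numpy()[m][:, prot]
            xc, tc = x - x.mean(axis=0), t - t.mean(axis=0)
            return float(np.corrcoef(xc.ravel(), tc.ravel())[0, 1])

        std, _ = run_standardisation(dataset)
        std_mn, _ = run_standardisation(
            dataset, ("hybridisation", "plate_scale", "median", "calibrate"))
        assert agreement(std_mn) < agreement(std)

    def test_tiny_bin_rejected(self):
        ds = make_dataset(np.full((3, 2), 100.0), dilution=[0.005, 0.2])
        with pytest.raises(StandardisationError, match="fewer than 2"):
            median_normalise(ds)


class TestRunStandardisation:
    def test_repeated_step_rejected(self, clean4):
        _, dataset, _ = clean4
        with pytest.raises(StandardisationError, match="repeated"):
            run_standardisation(dataset, ("hybridisation", "hybridisation"))

    def test_default_ladder_lowers_pooled_cv_per_step(self, clean4):
        _, dataset, _ = clean4

        def mean_cv(ds):
            return float(np.mean([percent_cv_table(ds, g).mean()
                                  for g in ("pooled_oa", "pooled_injury")]))

        cvs = [mean_cv(dataset)]
        cur = dataset
        for step in (hybridisation_normalise, plate_scale, calibrate):
            cur, _ = step(cur)
            cvs.append(mean_cv(cur))
        assert all(b < a for a, b in zip(cvs, cvs[1:]))

    def test_four_step_ladder_recorded_in_provenance(self, clean4):
        _, dataset, _ = clean4
        out, _ = run_standardisation(
            dataset, ("hybridisation", "plate_scale", "median", "calibrate"))
        steps = [p["steps"] for n, p in out.provenance if n == "run_standardisation"]
        assert steps == [["hybridisation", "plate_scale", "median", "calibrate"]]
        assert out.scale_state == "standardised"

    def test_stored_factors_reproduce_standardised_data(self, clean4):
        _, dataset, _ = clean4
        std, factors = run_standardisation(dataset)
        replay = factors.apply(dataset)
        np.testing.assert_allclose(replay.values, std.values, rtol=1e-12)


class TestAbundanceAndLog:
    def test_dilution_adjustment_arithmetic(self):
        rfu = np.tile([1000.0, 1000.0], (5, 1))
        ds = make_dataset(rfu, dilution=[0.005, 0.2], scale_state="standardised")
        ab = dilution_adjusted_abundance(ds)
        np.testing.assert_allclose(ab.to_numpy(), [200000.0, 5000.0])

    def test_abundance_tracks_generating_construction(self, clean4):
        _, dataset, truth = clean4
        std, _ = run_standardisation(dataset)
        ab = dilution_adjusted_abundance(std)
        prot = std.protein_mask()
        bins = std.somamers["dilution_bin"].to_numpy(dtype=float)
        expected = np.exp(truth.baseline.to_numpy()) / bins
        from scipy.stats import spearmanr
        rho = spearmanr(ab.to_numpy()[prot], expected[prot])[0]
        assert rho > 0.95

    @pytest.mark.parametrize("base,value,expected", [
        (None, np.e, 1.0), (2, 8.0, 3.0), (10, 1000.0, 3.0)])
    def test_log_worked_examples(self, base, value, expected):
        ds = make_dataset(np.full((2, 2), value), scale_state="standardised")
        out = log_transform(ds, base=base)
        np.testing.assert_allclose(out.values, expected, rtol=1e-12)

    def test_log_round_trip(self, clean4):
        _, dataset, _ = clean4
        back = exp_transform(log_transform(dataset))
        np.testing.assert_allclose(back.values, dataset.values, rtol=1e-12)

    def test_nonpositive_cell_named(self):
        ds = make_dataset(np.full((2, 2), 10.0), scale_state="standardised")
        ds.rfu.iloc[1, 1] = 0.0
        with pytest.raises(StandardisationError, match="S002.*SL002"):
            log_transform(ds)
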