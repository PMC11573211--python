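"""Intracellular protein score: weights, scoring, residualisation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sfsomaqc.batch_correct import correct_bimodal_and_plate, fit_pc2_gmm
from sfsomaqc.dimred import fit_pca
from sfsomaqc.ips import (
    IpsError,
    IpsModel,
    adjust_for_ips,
    compute_ips,
    compute_ips_weights,
    covariate_adjust,
)
from sfsomaqc.standardise import log_transform, run_standardisation
from conftest import make_dataset


def paired_toy(deltas: np.ndarray) -> "SomaDataset":  # noqa: F821
    """n_pairs x n_som matrix of unspun-minus-spun differences -> dataset."""
    n_pairs, _ = deltas.shape
    base = 8.0
    rows = []
    for j in range(n_pairs):
        rows.append(np.full(deltas.shape[1], base))          # spun
        rows.append(base + deltas[j])                        # unspun
    ds = make_dataset(np.array(rows), scale_state="log")
    ds.samples["participant_id"] = pd.array(
        [f"P{j:02d}" for j in range(n_pairs) for _ in range(2)], dtype="string")
    ds.samples["spun"] = pd.array([True, False] * n_pairs, dtype="boolean")
    return ds


class TestWeights:
    def test_hand_computed_cohens_d(self):
        deltas = np.array([[1.0], [1.0], [1.0], [3.0]])
        model = compute_ips_weights(paired_toy(deltas))
        assert model.weights.iloc[0] == pytest.approx(1.5)
        assert model.n_pairs == 4

    def test_zero_variance_differences_excluded_with_warning(self):
        deltas = np.ones((4, 3))
        with pytest.warns(UserWarning, match="empty IPS model"):
            model = compute_ips_weights(paired_toy(deltas))
        assert len(model.weights) == 0
        assert len(model.excluded) == 3

    def test_unmatched_pair_member_rejected(self):
        ds = paired_toy(np.array([[1.0], [2.0]]))
        ds.samples.loc[3, "participant_id"] = "ORPHAN"
        with pytest.raises(IpsError, match="unmatched"):
            compute_ips_weights(ds)

    def test_fewer_than_two_pairs_rejected(self):
        ds = paired_toy(np.array([[1.0]]))
        with pytest.raises(IpsError, match="2 complete pairs"):
            compute_ips_weights(ds)

    def test_weights_track_planted_loadings(self, clean4_paired):
        paired, truth = clean4_paired
        model = compute_ips_weights(log_transform(paired))
        lam = truth.intracellular_loading.loc[model.weights.index]
        rho = stats.spearmanr(model.weights.to_numpy(), lam.to_numpy())[0]
        assert rho > 0.9

    def test_pooled_sd_variant_differs_but_correlates(self, clean4_paired):
        paired, _ = clean4_paired
        logged = log_transform(paired)
        dz = compute_ips_weights(logged)
        pooled = compute_ips_weights(logged, variant="pooled")
        r = stats.pearsonr(dz.weights, pooled.weights.loc[dz.weights.index])[0]
        assert r > 0.85 and not np.allclose(dz.weights, pooled.weights)

    def test_model_json_round_trip(self, tmp_path, clean4_paired):
        paired, _ = clean4_paired
        model = compute_ips_weights(log_transform(paired))
        model.to_json(tmp_path / "ips.json")
        back = IpsModel.from_json(tmp_path / "ips.json")
        pd.testing.assert_series_equal(back.weights, model.weights,
                                       check_names=False)
        assert back.n_pairs == model.n_pairs


class TestScoring:
    def test_dot_product_example(self):
        ds = make_dataset(np.array([[2.0, 3.0]]), scale_state="log")
        model = IpsModel(weights=pd.Series({"SL001": 1.0, "SL002": -1.0}), n_pairs=4)
        assert compute_ips(ds, model).iloc[0] == pytest.approx(-1.0)

    def test_zero_weights_zero_scores(self):
        ds = make_dataset(np.random.default_rng(0).normal(8, 1, (5, 3)),
                          scale_state="log")
        model = IpsModel(weights=pd.Series(0.0, index=["SL001", "SL002", "SL003"]),
                         n_pairs=4)
        assert (compute_ips(ds, model) == 0).all()

    def test_missing_somamer_listed(self):
        ds = make_dataset(np.ones((2, 2)), scale_state="log")
        model = IpsModel(weights=pd.Series({"SL001": 1.0, "ABSENT": 2.0}), n_pairs=4)
        with pytest.raises(IpsError, match="ABSENT"):
            compute_ips(ds, model)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        w = pd.Series(rng.normal(0, 1, 4), index=[f"SL00{j}" for j in range(1, 5)])
        model = IpsModel(weights=w, n_pairs=4)
        c1, c2 = rng.normal(8, 1, (3, 4)), rng.normal(8, 1, (3, 4))
        a, b = 2.5, -1.25
        mix = compute_ips(make_dataset(a * c1 + b * c2, scale_state="log"), model)
        s1 = compute_ips(make_dataset(c1, scale_state="log"), model)
        s2 = compute_ips(make_dataset(c2, scale_state="log"), model)
        np.testing.assert_allclose(mix, a * s1 + b * s2, rtol=1e-10)

    def test_score_recovers_planted_factor(self, clean4, clean4_paired):
        _, dataset, truth = clean4
        paired, _ = clean4_paired
        model = compute_ips_weights(log_transform(paired))
        std, _ = run_standardisation(dataset)
        logged = log_transform(std)
        assignment = fit_pc2_gmm(fit_pca(logged).scores["PC2"], seed=0)
        corrected, _ = correct_bimodal_and_plate(logged, assignment)
        ips = compute_ips(corrected, model)
        u = truth.intracellular_score.loc[ips.index]
        assert stats.pearsonr(ips, u)[0] > 0.95

    def test_unspun_member_scores_higher_in_most_pairs(self, clean4_paired):
        paired, _ = clean4_paired
        logged = log_transform(paired)
        model = compute_ips_weights(logged)
        ips = compute_ips(logged, model)
        spun = ips.iloc[0::2].to_numpy()
        unspun = ips.iloc[1::2].to_numpy()
        assert (unspun > spun).sum() >= 16


class TestAdjustment:
    def test_collinear_somamer_flattens_to_mean(self):
        ips = pd.Series([1.0, 2.0, 3.0, 4.0], index=[f"S00{i}" for i in range(1, 5)])
        vals = np.column_stack([2 * ips.to_numpy() + 5, np.full(4, 7.0)])
        ds = make_dataset(vals, scale_state="log")
        out = adjust_for_ips(ds, ips.set_axis(ds.sample_ids))
        np.testing.assert_allclose(out.values[:, 0], vals[:, 0].mean(), atol=1e-10)

    def test_orthogonal_somamer_unchanged(self):
        ips = pd.Series([-1.0, 1.0, -1.0, 1.0])
        vals = np.array([[1.0], [1.0], [3.0], [3.0]])   # zero covariance with ips
        ds = make_dataset(vals, scale_state="log")
        out = adjust_for_ips(ds, ips.set_axis(ds.sample_ids))
        np.testing.assert_allclose(out.values, vals, atol=1e-12)

    def test_exact_decorrelation_and_mean_preservation(self, battery_run):
        corrected = battery_run.corrected
        ips = battery_run.ips_scores["with_ips"].loc[corrected.sample_ids]
        adj = adjust_for_ips(corrected, ips)
        vals = adj.values
        centred_ips = ips.to_numpy() - ips.mean()
        scale = np.abs(centred_ips).sum() * np.abs(vals).max()
        cov = centred_ips @ (vals - vals.mean(axis=0)) / (len(ips) - 1)
        assert np.abs(cov).max() < 1e-10 * scale
        np.testing.assert_allclose(adj.values.mean(axis=0),
                                   corrected.values.mean(axis=0), atol=1e-8)

    def test_constant_score_rejected(self):
        ds = make_dataset(np.random.default_rng(0).normal(8, 1, (4, 2)),
                          scale_state="log")
        with pytest.raises(IpsError, match="singular|constant"):
            adjust_for_ips(ds, pd.Series(1.0, index=ds.sample_ids))

    def test_pc1_decorrelated_after_adjustment(self, clean4, clean4_paired):
        _, dataset, truth = clean4
        paired, _ = clean4_paired
        model = compute_ips_weights(log_transform(paired))
        std, _ = run_standardisation(dataset)
        logged = log_transform(std)
        assignment = fit_pc2_gmm(fit_pca(logged).scores["PC2"], seed=0)
        corrected, _ = correct_bimodal_and_plate(logged, assignment)
        ips = compute_ips(corrected, model)
        before = fit_pca(corrected)
        adjusted = adjust_for_ips(corrected, ips)
        after = fit_pca(adjusted)
        r = stats.pearsonr(ips.loc[after.scores.index], after.scores["PC1"])[0]
        assert abs(r) < 0.05
        assert after.variance_explained[0] < 0.5 * before.variance_explained[0]


class TestCovariateAdjust:
    def test_single_covariate_equals_ips_adjustment(self):
        rng = np.random.default_rng(2)
        ds = make_dataset(rng.normal(8, 1, (20, 5)), scale_state="log")
        score = pd.Series(rng.normal(0, 1, 20), index=ds.sample_ids)
        a = adjust_for_ips(ds, score)
        b = covariate_adjust(ds, pd.DataFrame({"x": score}))
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_zero_covariates_identity(self):
        ds = make_dataset(np.random.default_rng(0).normal(8, 1, (5, 3)),
                          scale_state="log")
        out = covariate_adjust(ds, pd.DataFrame(index=ds.sample_ids))
        np.testing.assert_array_equal(out.values, ds.values)

    def test_rank_deficient_design_names_columns(self):
        rng = np.random.default_rng(3)
        ds = make_dataset(rng.normal(8, 1, (10, 2)), scale_state="log")
        x = rng.normal(0, 1, 10)
        cov = pd.DataFrame({"a": x, "b": 2 * x}, index=ds.sample_ids)
        with pytest.raises(IpsError, match="a.*b"):
            covariate_adjust(ds, cov)

    def test_planted_age_effect_nullified(self):
        """Residualising on age eliminates every in-sample age association
        (slopes collapse to zero; nothing survives BH)."""
        rng = np.random.default_rng(4)
        n, p = 400, 60
        age = rng.uniform(0, 10, n)
        vals = rng.normal(8, 0.3, (n, p))
        vals[:, :20] += 0.05 * age[:, None]
        ds = make_dataset(vals, scale_state="log")
        from statsmodels.stats.multitest import multipletests
        p_before = np.array([stats.linregress(age, vals[:, j]).pvalue
                             for j in range(p)])
        assert multipletests(p_before, method="fdr_bh")[0].sum() >= 19
        out = covariate_adjust(ds, pd.DataFrame({"age": age}, index=ds.sample_ids))
        slopes = np.array([stats.linregress(age, out.values[:, j]).slope
                           for j in range(p)])
        assert np.abs(slopes).max() < 1e-10
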