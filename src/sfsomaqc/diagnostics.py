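"""Validity checks: confounder-association maps, PC1-predictor regression,
spun/unspun paired comparison, and the haemoglobin-based blood score.

Continuous and ordinal confounders (blood grade enters as a linear ordinal
score) are tested against PCs by per-PC OLS; categorical confounders
(plate, processing batch) by one-way ANOVA.  Benjamini–Hochberg adjustment
is reported for exploratory tables and Bonferroni for anything that feeds
a filter.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import SomaDataset
from .dimred import PcaModel
from .ips import _paired_matrices
from .standardise import dilution_adjusted_abundance


class DiagnosticsError(ValueError):
    pass


def _bh(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests
    mask = np.isfinite(p)
    out = np.full_like(p, np.nan, dtype=float)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def associate_pcs_confounders(pca: PcaModel, confounders: pd.DataFrame,
                              categorical: tuple[str, ...] = (),
                              top_k: int = 10) -> pd.DataFrame:
    """Association of each top PC with each confounder.

    Continuous/ordinal columns: per-PC simple OLS slope test.  Columns named
    in *categorical*: one-way ANOVA F test.  Emits raw, Bonferroni- and
    BH-adjusted p-values (family = all (PC, confounder) cells tested).
    """
    k = min(top_k, pca.n_components)
    scores = pca.scores.iloc[:, :k]
    rows = []
    for name in confounders.columns:
        col = confounders[name]
        if name in categorical:
            labels = col.astype("object")
            mask = labels.notna().to_numpy()
        else:
            col = pd.to_numeric(col, errors="coerce")
            mask = np.isfinite(col.to_numpy(dtype=float))
        n = int(mask.sum())
        if n < 10:
            warnings.warn(f"confounder {name!r}: only {n} complete cases; skipped")
            continue
        for pc in scores.columns:
            y = scores[pc].to_numpy(dtype=float)[mask]
            if name in categorical:
                groups = [y[(labels[mask] == g).to_numpy()]
                          for g in pd.unique(labels[mask])]
                groups = [g for g in groups if len(g) > 0]
                if len(groups) < 2:
                    stat, p = np.nan, np.nan
                else:
                    stat, p = stats.f_oneway(*groups)
            else:
                x = col.to_numpy(dtype=float)[mask]
                if np.ptp(x) == 0:
                    stat, p = np.nan, np.nan
                else:
                    res = stats.linregress(x, y)
                    stat, p = res.slope / res.stderr if res.stderr > 0 else np.nan, res.pvalue
            rows.append({"confounder": name, "pc": pc, "statistic": float(stat)
                         if np.isfinite(stat) else np.nan, "p": p, "n": n})
    table = pd.DataFrame(rows)
    if len(table):
        m = table["p"].notna().sum()
        table["p_bonferroni"] = np.minimum(table["p"] * m, 1.0)
        table["p_bh"] = _bh(table["p"].to_numpy(dtype=float))
    return table


def pc1_predictor_regression(dataset: SomaDataset, pca: PcaModel,
                             abundance: pd.Series | None = None) -> pd.DataFrame:
    """What predicts a protein's correlation with PC1?

    Per SOMAmer, r_p = Pearson(PC1 scores, C_.p); multiple OLS of r_p on log
    dilution-adjusted abundance plus secretion-class indicators.  Returns
    the coefficient table (coef, se, t, p).
    """
    import statsmodels.api as sm

    scores = pca.scores["PC1"]
    ids = scores.index
    sub = dataset.rfu.loc[dataset.samples["sample_id"].astype(str).isin(ids).to_numpy()]
    x = scores.to_numpy(dtype=float)
    y = sub.to_numpy(dtype=float)
    xc = x - x.mean()
    yc = y - y.mean(axis=0)
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (xc @ yc) / denom, np.nan)

    if abundance is None:
        abundance = dilution_adjusted_abundance(
            dataset if dataset.scale_state in ("raw", "standardised")
            else dataset.with_values(np.exp(dataset.values), scale_state="standardised"))
    log_ab = np.log(abundance.to_numpy(dtype=float))

    sec = dataset.somamers["secretion_class"].astype(str)
    design = pd.DataFrame({"log_abundance": log_ab})
    present = [c for c in ("nuclear_not_secreted", "not_secreted_other", "unknown")
               if (sec == c).any()]
    if not present:
        warnings.warn("single secretion class present: indicators dropped")
    for c in present:
        design[c] = (sec == c).astype(float).to_numpy()
    keep = np.isfinite(r) & np.isfinite(log_ab)
    model = sm.OLS(r[keep], sm.add_constant(design.loc[keep])).fit()
    return pd.DataFrame({"coef": model.params, "se": model.bse,
                         "t": model.tvalues, "p": model.pvalues})


def spun_unspun_comparison(paired_dataset: SomaDataset,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Per-SOMAmer paired comparison of spun vs unspun aliquots.

    Returns Cohen's d (paired d_z), two-sided paired t-test p, Pearson r
    across pairs, BH-adjusted p within each test family, and the
    quadrant classification (different means x correlated).
    """
    spun, unspun, n_pairs = _paired_matrices(paired_dataset)
    if n_pairs < 3:
        raise DiagnosticsError(f"need >= 3 complete pairs, got {n_pairs}")
    delta = unspun - spun
    mean_d = delta.mean(axis=0)
    sd_d = delta.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(sd_d > 0, mean_d / sd_d, np.nan)
    t = d * np.sqrt(n_pairs)
    p_t = 2 * stats.t.sf(np.abs(t), df=n_pairs - 1)

    sc = spun - spun.mean(axis=0)
    uc = unspun - unspun.mean(axis=0)
    denom = np.sqrt((sc ** 2).sum(axis=0) * (uc ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (sc * uc).sum(axis=0) / denom, np.nan)
    r = np.clip(r, -1, 1)
    t_r = r * np.sqrt(np.maximum(n_pairs - 2, 1)) / np.sqrt(np.maximum(1 - r ** 2, 1e-300))
    p_r = 2 * stats.t.sf(np.abs(t_r), df=n_pairs - 2)

    q_t, q_r = _bh(p_t), _bh(p_r)
    table = pd.DataFrame({
        "cohens_d": d, "p_ttest": p_t, "p_ttest_bh": q_t,
        "pearson_r": r, "p_corr": p_r, "p_corr_bh": q_r,
        "different_means": q_t < alpha, "correlated": q_r < alpha,
    }, index=paired_dataset.seq_ids)
    return table


def blood_score(dataset: SomaDataset, hba_seq_id: str
                ) -> tuple[pd.Series, float]:
    """Per-sample blood-content score: log standardised RFU of haemoglobin A.

    Returns the score and its Spearman rho against the recorded visual
    blood-staining grade (ordinal, over samples with a grade).  Warns if
    given IPS-adjusted input — the score is defined on non-adjusted data.
    """
    if hba_seq_id not in dataset.rfu.columns:
        raise DiagnosticsError(f"HBA SOMAmer {hba_seq_id!r} absent from dataset")
    if dataset.scale_state == "adjusted":
        warnings.warn("blood score is defined on non-IPS-adjusted data; "
                      "input is 'adjusted'")
    vals = dataset.rfu[hba_seq_id].to_numpy(dtype=float)
    if dataset.scale_state in ("raw", "standardised"):
        vals = np.log(vals)
    score = pd.Series(vals, index=dataset.sample_ids, name="blood_score")
    grades = pd.to_numeric(dataset.samples["blood_grade"], errors="coerce")
    mask = np.isfinite(grades.to_numpy(dtype=float))
    if mask.sum() >= 3 and np.ptp(grades.to_numpy(dtype=float)[mask]) > 0:
        rho = float(stats.spearmanr(vals[mask], grades.to_numpy(dtype=float)[mask])[0])
    else:
        rho = float("nan")
    return score, rho
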