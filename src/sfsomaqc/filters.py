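"""SOMAmer and sample filter battery with LOD computation and audit report.

Fixed application order (each step sees the survivors of the previous one):

SOMAmer filters
    1. control reagents / non-human targets;
    2. confounder association (per-confounder Bonferroni across SOMAmers);
    3. non-technical R² below threshold in either pooled group.

Sample filters (study and pooled wells only; assay controls are exempt)
    4. vendor QC flag;
    5. >25% of protein values outside the limits of detection;
    6. total RFU beyond 5 SD of the study-sample mean;
    7. beyond 5 SD on any top principal component (PCA refit on survivors).

Boundary conventions are strict inequalities throughout ("more than 25%",
"beyond 5 SD", "less than 50%").  The lower LOD is
median(blanks) + 4.9 x MAD(blanks) with *unscaled* MAD (the 4.9 multiplier
is calibrated to the raw median absolute deviation); the upper LOD is a
fixed 80,000 RFU saturation ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import SomaDataset
from .dimred import fit_pca, top_pcs_at_threshold
from .qc_metrics import repeatability

DEFAULT_UPPER_LOD = 80_000.0


class FilterError(ValueError):
    pass


@dataclass
class LodTable:
    """Per-(plate, SOMAmer) detection limits derived from plate blanks."""

    lower: pd.DataFrame                    # plate_id x seq_id
    upper: float = DEFAULT_UPPER_LOD

    def limits_for(self, plate: str) -> pd.Series:
        return self.lower.loc[plate]


def compute_lod(dataset: SomaDataset, upper: float = DEFAULT_UPPER_LOD) -> LodTable:
    """Lower LOD = median(blanks) + 4.9 * MAD(blanks) per plate and SOMAmer.

    MAD is the raw median absolute deviation (no 1.4826 normal-consistency
    scaling).  Requires >= 3 blank wells per plate, on the standardised
    linear scale.
    """
    if dataset.scale_state not in ("raw", "standardised"):
        raise FilterError("LOD is defined on the linear scale")
    blanks = dataset.role_mask("blank")
    plate = dataset.samples["plate_id"].astype(str).to_numpy()
    plates = pd.unique(plate)
    rows = {}
    values = dataset.values
    for q in plates:
        mask = blanks & (plate == q)
        if mask.sum() < 3:
            raise FilterError(f"plate {q} has {int(mask.sum())} blanks (<3 required)")
        b = values[mask]
        med = np.median(b, axis=0)
        mad = np.median(np.abs(b - med[None, :]), axis=0)
        rows[q] = med + 4.9 * mad
    lower = pd.DataFrame(rows, index=dataset.seq_ids).T
    return LodTable(lower=lower, upper=float(upper))


def _filterable(dataset: SomaDataset) -> np.ndarray:
    """Samples subject to sample filters: study + pooled wells."""
    return dataset.study_mask(include_pooled=True)


def filter_samples_lod(dataset: SomaDataset, lod: LodTable,
                       max_fraction: float = 0.25) -> set[str]:
    """Samples with more than *max_fraction* of protein values outside LOD."""
    prot = dataset.protein_mask()
    values = dataset.values[:, prot]
    lower = lod.lower.loc[:, dataset.seq_ids[prot]]
    plate = dataset.samples["plate_id"].astype(str).to_numpy()
    lo = lower.loc[plate].to_numpy()
    frac = ((values < lo) | (values > lod.upper)).mean(axis=1)
    mask = _filterable(dataset) & (frac > max_fraction)
    return set(dataset.sample_ids[mask])


def filter_samples_total_rfu(dataset: SomaDataset, n_sd: float = 5.0) -> set[str]:
    """Samples whose total protein RFU is beyond n_sd SD of the study mean."""
    prot = dataset.protein_mask()
    totals = dataset.values[:, prot].sum(axis=1)
    study = dataset.study_mask()
    m, s = totals[study].mean(), totals[study].std(ddof=1)
    if s == 0:
        return set()
    mask = _filterable(dataset) & (np.abs(totals - m) > n_sd * s)
    return set(dataset.sample_ids[mask])


def filter_samples_pca(dataset: SomaDataset, n_sd: float = 5.0,
                       threshold: float = 0.80) -> set[str]:
    """Samples beyond n_sd SD on any of the top PCs covering *threshold*
    of variance.  PCA is fit on the current study+pooled samples."""
    model = fit_pca(dataset)
    k = top_pcs_at_threshold(model, threshold)
    scores = model.scores.iloc[:, :k].to_numpy()
    sd = scores.std(axis=0, ddof=1)
    out = np.abs(scores) > n_sd * sd[None, :]
    bad = model.scores.index[out.any(axis=1)]
    return set(map(str, bad))


def filter_samples_flagged(dataset: SomaDataset) -> set[str]:
    """Samples carrying the vendor in-house QC flag (controls exempt)."""
    flag = dataset.samples["vendor_flag"].fillna(False).astype(bool).to_numpy()
    mask = _filterable(dataset) & flag
    return set(dataset.sample_ids[mask])


def filter_somamers_control(dataset: SomaDataset) -> set[str]:
    """Non-human targets and control reagent types."""
    keep = dataset.protein_mask()
    return set(dataset.seq_ids[~keep])


def filter_somamers_confounder(dataset: SomaDataset, confounders: pd.DataFrame,
                               alpha: float = 0.05) -> set[str]:
    """SOMAmers associated with any listed confounder at Bonferroni-adjusted
    p < alpha (per-confounder family = all SOMAmers tested).

    Simple per-SOMAmer OLS slope test on complete-case study samples.
    """
    if dataset.scale_state not in ("log", "adjusted"):
        raise FilterError("confounder filter operates on log-scale data")
    study = dataset.study_mask()
    values = dataset.values
    removed: set[str] = set()
    n_som = values.shape[1]
    for name in confounders.columns:
        x_all = pd.to_numeric(confounders[name], errors="coerce").to_numpy(dtype=float)
        mask = study & np.isfinite(x_all)
        n = int(mask.sum())
        if n < 10:
            raise FilterError(f"confounder {name!r} has {n} non-missing values (<10)")
        x = x_all[mask]
        if np.ptp(x) == 0:
            raise FilterError(f"confounder {name!r} is constant")
        y = values[mask]
        xc = x - x.mean()
        yc = y - y.mean(axis=0)
        denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (xc @ yc) / denom
        r = np.clip(np.nan_to_num(r), -1.0, 1.0)
        t = r * np.sqrt(n - 2) / np.sqrt(np.maximum(1 - r ** 2, 1e-300))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
        p_adj = np.minimum(p * n_som, 1.0)
        removed |= set(dataset.seq_ids[p_adj < alpha])
    return removed


def filter_somamers_r2(r2_oa: pd.Series, r2_injury: pd.Series,
                       min_r2: float = 0.5) -> set[str]:
    """SOMAmers whose non-technical R² is below *min_r2* in either group."""
    missing = set(r2_oa.index) ^ set(r2_injury.index)
    if missing:
        raise FilterError(f"SOMAmers missing from one R² table: {sorted(missing)[:10]}")
    both = pd.concat({"oa": r2_oa, "injury": r2_injury}, axis=1)
    bad = both.min(axis=1) < min_r2
    return set(both.index[bad].astype(str))


@dataclass
class FilterConfig:
    confounders: tuple[str, ...] = ("sample_age_years", "freeze_thaw_count")
    confounder_alpha: float = 0.05
    min_r2: float = 0.5
    r2_formula: str = "one_minus_ratio_squared"
    lod_max_fraction: float = 0.25
    upper_lod: float = DEFAULT_UPPER_LOD
    total_rfu_n_sd: float = 5.0
    pca_n_sd: float = 5.0
    pca_threshold: float = 0.80


@dataclass
class FilterReport:
    """Ordered audit trail of every filter applied."""

    entries: list[dict[str, Any]] = field(default_factory=list)

    def record(self, name: str, params: dict[str, Any], removed: set[str],
               n_samples: int, n_somamers: int) -> None:
        self.entries.append({
            "filter": name, "parameters": params,
            "removed_ids": sorted(removed), "n_removed": len(removed),
            "surviving_samples": n_samples, "surviving_somamers": n_somamers,
        })

    def removed(self, name: str) -> set[str]:
        for e in self.entries:
            if e["filter"] == name:
                return set(e["removed_ids"])
        raise KeyError(name)

    @property
    def final_counts(self) -> tuple[int, int]:
        last = self.entries[-1]
        return last["surviving_samples"], last["surviving_somamers"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{k: e[k] for k in
                              ("filter", "n_removed", "surviving_samples",
                               "surviving_somamers")} for e in self.entries])

    def to_json_dict(self) -> dict[str, Any]:
        return {"entries": self.entries}


def apply_filters(dataset: SomaDataset, linear: SomaDataset,
                  config: FilterConfig | None = None
                  ) -> tuple[SomaDataset, FilterReport]:
    """Run the full battery in fixed order with an audit report.

    Parameters
    ----------
    dataset
        Batch-corrected log-scale dataset (drives confounder, R² and PCA
        filters).
    linear
        Companion standardised linear-scale dataset with the same SOMAmers
        and at least the same samples (drives LOD and total-RFU filters;
        must additionally carry the blank wells for LOD).
    """
    cfg = config or FilterConfig()
    if not set(dataset.sample_ids) <= set(linear.sample_ids):
        raise FilterError("linear dataset is missing samples of the log dataset")
    if list(dataset.seq_ids) != list(linear.seq_ids):
        raise FilterError("log and linear datasets have different SOMAmers")
    report = FilterReport()
    cur, cur_lin = dataset, linear

    def counts() -> tuple[int, int]:
        return len(cur.samples), len(cur.somamers)

    def drop_somamers(removed: set[str]) -> None:
        nonlocal cur, cur_lin
        if removed:
            keep = [s for s in cur.seq_ids if s not in removed]
            cur, cur_lin = cur.subset(seq_ids=keep), cur_lin.subset(seq_ids=keep)

    def drop_samples(removed: set[str]) -> None:
        nonlocal cur, cur_lin
        if removed:
            keep = [s for s in cur.sample_ids if s not in removed]
            cur = cur.subset(sample_ids=keep)
            keep_lin = [s for s in cur_lin.sample_ids if s not in removed]
            cur_lin = cur_lin.subset(sample_ids=keep_lin)

    # --- SOMAmer filters ---
    rm = filter_somamers_control(cur)
    drop_somamers(rm)
    report.record("control_somamers", {}, rm, *counts())

    conf = cur.samples[list(cfg.confounders)]
    rm = filter_somamers_confounder(cur, conf, alpha=cfg.confounder_alpha)
    drop_somamers(rm)
    report.record("confounder_somamers",
                  {"confounders": list(cfg.confounders), "alpha": cfg.confounder_alpha},
                  rm, *counts())

    rep = repeatability(cur_lin.subset(sample_ids=list(cur.sample_ids)),
                        dataset_log=cur, formula=cfg.r2_formula)
    rm = filter_somamers_r2(rep.r2["pooled_oa"], rep.r2["pooled_injury"],
                            min_r2=cfg.min_r2)
    drop_somamers(rm)
    report.record("low_r2_somamers",
                  {"min_r2": cfg.min_r2, "formula": cfg.r2_formula}, rm, *counts())

    # --- sample filters (restricted to the current analysis set) ---
    rm = filter_samples_flagged(cur)
    drop_samples(rm)
    report.record("vendor_flagged_samples", {}, rm, *counts())

    lod = compute_lod(cur_lin, upper=cfg.upper_lod)
    rm = filter_samples_lod(cur_lin, lod, max_fraction=cfg.lod_max_fraction)
    rm &= set(cur.sample_ids)
    drop_samples(rm)
    report.record("lod_samples",
                  {"max_fraction": cfg.lod_max_fraction, "upper_lod": cfg.upper_lod},
                  rm, *counts())

    rm = filter_samples_total_rfu(cur_lin, n_sd=cfg.total_rfu_n_sd)
    rm &= set(cur.sample_ids)
    drop_samples(rm)
    report.record("total_rfu_samples", {"n_sd": cfg.total_rfu_n_sd}, rm, *counts())

    rm = filter_samples_pca(cur, n_sd=cfg.pca_n_sd, threshold=cfg.pca_threshold)
    drop_samples(rm)
    report.record("pca_outlier_samples",
                  {"n_sd": cfg.pca_n_sd, "threshold": cfg.pca_threshold},
                  rm, *counts())

    cur.log_op("apply_filters", final_samples=counts()[0], final_somamers=counts()[1])
    return cur, report
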