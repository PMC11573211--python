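"""Repeatability and accuracy metrics: %CV, non-technical R², immunoassay concordance.

%CV is computed on linear standardised RFU (vendor convention); the
non-technical R² compares pooled-replicate variance against the variance of
individual study samples on the log scale.  Two printed variants of the R²
formula circulate for this assay; both are implemented and the choice is
recorded in provenance (see :func:`nontechnical_r2`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import SomaDataset

R2_FORMULAS = ("one_minus_ratio_squared", "squared_one_minus_ratio")


def percent_cv(values: np.ndarray) -> float:
    """100 * sd/mean of replicate measurements (sample sd, n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("percent_cv needs at least 2 replicates")
    m = x.mean()
    if m <= 0:
        raise ValueError(f"percent_cv undefined for non-positive mean {m}")
    return float(100.0 * x.std(ddof=1) / m)


def percent_cv_table(dataset: SomaDataset, role: str = "pooled_oa",
                     log_scale: bool = False) -> pd.Series:
    """Per-SOMAmer %CV across the pooled replicate wells of one group."""
    mask = dataset.role_mask(role)
    if mask.sum() < 2:
        raise ValueError(f"fewer than 2 replicates with role {role!r}")
    values = dataset.values[mask]
    if log_scale:
        values = np.log(values)
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    if np.any(means <= 0):
        raise ValueError("non-positive replicate mean; %CV undefined")
    return pd.Series(100.0 * sds / means, index=dataset.seq_ids, name=f"cv_{role}")


def nontechnical_r2(pooled_values: np.ndarray, all_sample_values: np.ndarray,
                    formula: str = "one_minus_ratio_squared") -> float:
    """Estimated fraction of variance that is not technical.

    With V_pooled the variance across pooled replicates and V_total the
    variance across individual study samples:

    * ``one_minus_ratio_squared`` (default): 1 - (V_pooled/V_total)^2
    * ``squared_one_minus_ratio``: (1 - V_pooled/V_total)^2

    Returns NaN (flagged undefined) when V_total is zero.
    """
    if formula not in R2_FORMULAS:
        raise ValueError(f"unknown formula {formula!r}; choose from {R2_FORMULAS}")
    vp = float(np.var(np.asarray(pooled_values, dtype=float), ddof=1))
    vt = float(np.var(np.asarray(all_sample_values, dtype=float), ddof=1))
    if vt == 0:
        return float("nan")
    ratio = vp / vt
    if formula == "one_minus_ratio_squared":
        return 1.0 - ratio ** 2
    return (1.0 - ratio) ** 2


@dataclass
class RepeatabilityTable:
    """Per-SOMAmer repeatability metrics per pooled group."""

    cv: pd.DataFrame        # seq_id x group, percent
    r2: pd.DataFrame        # seq_id x group, fraction (may be negative)
    formula: str

    @property
    def flagged_negative_r2(self) -> pd.Index:
        return self.r2.index[(self.r2 < 0).any(axis=1)]


def repeatability(dataset_linear: SomaDataset, dataset_log: SomaDataset | None = None,
                  groups: tuple[str, ...] = ("pooled_oa", "pooled_injury"),
                  formula: str = "one_minus_ratio_squared") -> RepeatabilityTable:
    """%CV (linear scale) and non-technical R² (log scale) per pooled group.

    ``dataset_log`` defaults to the elementwise log of ``dataset_linear``.
    V_total uses all individual (non-pooled, non-control) study samples.
    """
    if dataset_log is None:
        logv = np.log(dataset_linear.values)
    else:
        logv = dataset_log.values
    study = dataset_linear.study_mask()
    cv_cols, r2_cols = {}, {}
    for g in groups:
        cv_cols[g] = percent_cv_table(dataset_linear, role=g)
        mask = dataset_linear.role_mask(g)
        vp = np.var(logv[mask], axis=0, ddof=1)
        vt = np.var(logv[study], axis=0, ddof=1)
        ratio = np.divide(vp, vt, out=np.full_like(vp, np.nan), where=vt > 0)
        if formula == "one_minus_ratio_squared":
            r2 = 1.0 - ratio ** 2
        elif formula == "squared_one_minus_ratio":
            r2 = (1.0 - ratio) ** 2
        else:
            raise ValueError(f"unknown formula {formula!r}")
        r2_cols[g] = pd.Series(r2, index=dataset_linear.seq_ids)
    return RepeatabilityTable(cv=pd.DataFrame(cv_cols), r2=pd.DataFrame(r2_cols),
                              formula=formula)


def immunoassay_concordance(dataset: SomaDataset, immunoassay: pd.DataFrame,
                            analyte_map: dict[str, str],
                            group: str | None = None) -> pd.DataFrame:
    """Per-analyte Pearson r (log-log) with Fisher-z 95% CI.

    Parameters
    ----------
    immunoassay
        Long table with columns ``analyte``, ``sample_id``, ``concentration``
        (absolute units, positive).
    analyte_map
        analyte name -> seq_id.
    group
        Optional disease group to stratify on.

    Analytes with fewer than 4 overlapping samples are skipped (reported
    with NaN r and ``n`` giving the overlap found).
    """
    values = dataset.rfu
    meta = dataset.samples
    rows = []
    for analyte, seq_id in analyte_map.items():
        if seq_id not in values.columns:
            raise KeyError(f"seq_id {seq_id} for analyte {analyte} not in dataset")
        sub = immunoassay[immunoassay["analyte"] == analyte]
        idx = meta["sample_id"].astype(str)
        keep = idx.isin(sub["sample_id"].astype(str))
        if group is not None:
            keep &= meta["disease_group"] == group
        ids = idx[keep]
        n = int(keep.sum())
        if n < 4:
            rows.append({"analyte": analyte, "seq_id": seq_id, "n": n,
                         "r": np.nan, "ci_low": np.nan, "ci_high": np.nan})
            continue
        soma = values.loc[keep.to_numpy(), seq_id].to_numpy(dtype=float)
        if dataset.scale_state not in ("log", "adjusted"):
            soma = np.log(soma)
        conc = sub.set_index(sub["sample_id"].astype(str)).loc[ids, "concentration"]
        conc = np.log(conc.to_numpy(dtype=float))
        r, _ = stats.pearsonr(soma, conc)
        z = np.arctanh(np.clip(r, -0.999999, 0.999999))
        se = 1.0 / np.sqrt(n - 3)
        lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
        rows.append({"analyte": analyte, "seq_id": seq_id, "n": n,
                     "r": float(r), "ci_low": float(lo), "ci_high": float(hi)})
    return pd.DataFrame(rows)
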