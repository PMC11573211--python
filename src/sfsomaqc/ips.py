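"""Intracellular Protein Score (IPS): estimation, scoring, residualisation.

Synovial fluid carries a variable admixture of intracellular protein (cell
turnover, lysis at aspiration, or microvesicles).  On this assay it appears
as a dominant principal component loading mostly on low-abundance,
non-secreted proteins.  The IPS quantifies it per sample as a weighted sum
of log concentrations,

    IPS_i = sum_p d_p * C_ip,

where the weight d_p is the paired Cohen's d (d_z form: mean over pairs of
the log-concentration difference, divided by its sd) between aliquots that
were left unspun versus centrifuged before freezing.  Higher IPS means more
intracellular signal.  Weights are estimated once, on the paired subset,
and frozen; scoring never re-estimates them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import SomaDataset


class IpsError(ValueError):
    pass


@dataclass
class IpsModel:
    """Per-SOMAmer weights ``d_p`` plus bookkeeping."""

    weights: pd.Series                       # seq_id -> d_p
    n_pairs: int
    excluded: dict[str, str] = field(default_factory=dict)  # seq_id -> reason
    scale_note: str = "log(e)"
    variant: str = "paired_dz"

    def to_json(self, path: str | Path) -> None:
        payload = {"weights": {k: float(v) for k, v in self.weights.items()},
                   "n_pairs": self.n_pairs, "excluded": self.excluded,
                   "scale_note": self.scale_note, "variant": self.variant}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "IpsModel":
        d = json.loads(Path(path).read_text())
        return cls(weights=pd.Series(d["weights"], dtype=float), n_pairs=d["n_pairs"],
                   excluded=d.get("excluded", {}), scale_note=d.get("scale_note", "log(e)"),
                   variant=d.get("variant", "paired_dz"))


def _paired_matrices(dataset: SomaDataset) -> tuple[np.ndarray, np.ndarray, int]:
    """(spun, unspun) log matrices aligned by participant_id."""
    meta = dataset.samples
    spun_flag = meta["spun"].astype("boolean")
    if spun_flag.isna().any():
        bad = meta.loc[spun_flag.isna(), "sample_id"].tolist()
        raise IpsError(f"samples with missing spun status: {bad}")
    pids = meta["participant_id"].astype(str)
    values = dataset.values
    spun_rows, unspun_rows = {}, {}
    for i, (pid, s) in enumerate(zip(pids, spun_flag)):
        (spun_rows if bool(s) else unspun_rows)[pid] = i
    common = sorted(set(spun_rows) & set(unspun_rows))
    unmatched = sorted(set(spun_rows) ^ set(unspun_rows))
    if unmatched:
        raise IpsError(f"unmatched pair members for participants: {unmatched}")
    if len(common) < 2:
        raise IpsError(f"need >= 2 complete pairs, got {len(common)}")
    s_idx = [spun_rows[p] for p in common]
    u_idx = [unspun_rows[p] for p in common]
    return values[s_idx], values[u_idx], len(common)


def compute_ips_weights(paired_dataset: SomaDataset,
                        variant: str = "paired_dz") -> IpsModel:
    """Estimate d_p from a log-scale dataset of paired spun/unspun samples.

    ``variant='paired_dz'`` (default) uses mean(diff)/sd(diff); ``'pooled'``
    divides the mean difference by the pooled sd of the two arms instead.
    SOMAmers whose difference has zero variance are excluded and listed.
    """
    if paired_dataset.scale_state not in ("log", "adjusted"):
        raise IpsError("IPS weights are defined on log-scale data")
    spun, unspun, n_pairs = _paired_matrices(paired_dataset)
    delta = unspun - spun
    mean_d = delta.mean(axis=0)
    seq_ids = paired_dataset.seq_ids
    if variant == "paired_dz":
        sd = delta.std(axis=0, ddof=1)
    elif variant == "pooled":
        sd = np.sqrt((spun.var(axis=0, ddof=1) + unspun.var(axis=0, ddof=1)) / 2.0)
    else:
        raise IpsError(f"unknown Cohen's d variant {variant!r}")
    zero = sd == 0
    d = np.divide(mean_d, sd, out=np.zeros_like(mean_d), where=~zero)
    weights = pd.Series(d[~zero], index=seq_ids[~zero], name="d_p")
    excluded = {str(s): "zero-variance paired difference" for s in seq_ids[zero]}
    if len(weights) == 0:
        import warnings
        warnings.warn("all SOMAmers excluded (zero-variance differences); empty IPS model")
    return IpsModel(weights=weights, n_pairs=n_pairs, excluded=excluded, variant=variant)


def compute_ips(dataset: SomaDataset, model: IpsModel) -> pd.Series:
    """Score every sample: IPS_i = sum_p d_p C_ip over the model's SOMAmers."""
    if dataset.scale_state not in ("log", "adjusted"):
        raise IpsError("IPS is defined on log-scale data")
    missing = [s for s in model.weights.index if s not in dataset.rfu.columns]
    if missing:
        raise IpsError(f"dataset lacks model SOMAmers: {missing[:10]}"
                       + ("..." if len(missing) > 10 else ""))
    sub = dataset.rfu[list(model.weights.index)].to_numpy(dtype=float)
    scores = sub @ model.weights.to_numpy()
    return pd.Series(scores, index=dataset.sample_ids, name="ips")


def adjust_for_ips(dataset: SomaDataset, ips: pd.Series) -> SomaDataset:
    """Residualise every SOMAmer on the centred IPS, preserving its mean.

    Per SOMAmer, ordinary least squares of C_.p on the centred score; the
    value is replaced by residual + overall mean.  Afterwards every SOMAmer
    has exactly zero sample covariance with the score.
    """
    return covariate_adjust(dataset, pd.DataFrame({"ips": ips}))


def covariate_adjust(dataset: SomaDataset, covariates: pd.DataFrame) -> SomaDataset:
    """Joint OLS residualisation of every SOMAmer on continuous covariates.

    Covariates are aligned to samples by index (falling back to positional
    order when indices do not match), centred, and must be complete for all
    samples.  Zero covariates is the identity.
    """
    if dataset.scale_state not in ("log", "adjusted"):
        raise IpsError("covariate adjustment operates on log-scale data")
    out = dataset.copy()
    if covariates.shape[1] == 0:
        out.log_op("covariate_adjust", covariates=[])
        return out
    sample_ids = dataset.sample_ids
    if set(sample_ids) <= set(map(str, covariates.index)):
        cov = covariates.loc[sample_ids].to_numpy(dtype=float)
    elif len(covariates) == len(sample_ids):
        cov = covariates.to_numpy(dtype=float)
    else:
        raise IpsError("covariates do not align with dataset samples")
    if np.isnan(cov).any():
        raise IpsError("covariates contain missing values (complete-case required)")
    x = cov - cov.mean(axis=0)
    if np.allclose(x, 0):
        raise IpsError("covariate(s) constant across samples: design is singular")
    q, r = np.linalg.qr(x)
    rank = np.sum(np.abs(np.diag(r)) > 1e-10 * np.abs(r[0, 0] if r.size else 1))
    if rank < x.shape[1]:
        raise IpsError(
            f"rank-deficient design: collinear columns among {list(covariates.columns)}")
    values = dataset.values
    means = values.mean(axis=0)
    centred = values - means[None, :]
    resid = centred - q @ (q.T @ centred)
    out.rfu = pd.DataFrame(resid + means[None, :], index=dataset.rfu.index,
                           columns=dataset.rfu.columns)
    out.scale_state = "adjusted"
    out.log_op("covariate_adjust", covariates=list(map(str, covariates.columns)))
    return out
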