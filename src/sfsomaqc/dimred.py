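"""PCA of the sample x SOMAmer log matrix, variance accounting, and an
optional UMAP wrapper for visualisation.

PCA is computed by SVD with centring only by default (unit-variance
scaling available by flag) and a deterministic sign convention: the
largest-magnitude element of each loading vector is positive.  By
convention the fit set is the study + pooled samples — calibrators, plasma
QC wells and blanks describe plasma, not synovial fluid — but any matrix
can be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import SomaDataset


class DimredError(ValueError):
    pass


@dataclass
class PcaModel:
    mean: np.ndarray                   # per-feature centring vector
    scale: np.ndarray | None           # per-feature scaling vector (or None)
    loadings: pd.DataFrame             # feature x component
    scores: pd.DataFrame               # sample x component
    variance_explained: np.ndarray     # fractions, nonincreasing

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, dataset: SomaDataset) -> pd.DataFrame:
        """Project new samples onto the fitted components."""
        x = dataset.rfu[self.loadings.index].to_numpy(dtype=float) - self.mean[None, :]
        if self.scale is not None:
            x = x / self.scale[None, :]
        return pd.DataFrame(x @ self.loadings.to_numpy(),
                            index=dataset.sample_ids, columns=self.loadings.columns)


def fit_pca(dataset: SomaDataset, scale: bool = False,
            sample_mask: np.ndarray | None = None,
            n_components: int | None = None) -> PcaModel:
    """PCA of the (log-scale) matrix over study + pooled samples.

    Parameters
    ----------
    scale
        Unit-variance scale features after centring (default off: on log
        data the abundance structure of the loadings is itself diagnostic).
    sample_mask
        Overrides the default study+pooled fit set.
    """
    if dataset.scale_state not in ("log", "adjusted"):
        raise DimredError("PCA expects log-scale data")
    mask = dataset.study_mask(include_pooled=True) if sample_mask is None else sample_mask
    x = dataset.values[mask]
    ids = dataset.sample_ids[mask]
    if x.shape[0] < 2:
        raise DimredError("PCA needs at least 2 samples")
    mean = x.mean(axis=0)
    xc = x - mean[None, :]
    sd = None
    if scale:
        sd = xc.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise DimredError("constant feature: cannot unit-scale")
        xc = xc / sd[None, :]
    if np.allclose(xc, 0):
        raise DimredError("constant matrix: PCA undefined")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    if n_components is not None:
        u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    # deterministic sign: largest-|.| element of each loading vector positive
    flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    comp_names = [f"PC{k + 1}" for k in range(len(s))]
    var = s ** 2
    return PcaModel(
        mean=mean, scale=sd,
        loadings=pd.DataFrame(vt.T, index=dataset.seq_ids, columns=comp_names),
        scores=pd.DataFrame(u * s[None, :], index=ids, columns=comp_names),
        variance_explained=var / var.sum())


def top_pcs_at_threshold(model: PcaModel, threshold: float = 0.80) -> int:
    """Smallest k whose cumulative variance fraction reaches *threshold*."""
    if not 0 < threshold <= 1:
        raise DimredError(f"threshold must be in (0, 1], got {threshold}")
    cum = np.cumsum(model.variance_explained)
    return int(np.searchsorted(cum, threshold - 1e-12) + 1)


def umap_embed(model: PcaModel, k: int, seed: int = 0) -> pd.DataFrame:
    """2-D UMAP embedding of the top-k PC scores (visualisation only;
    delegated to umap-learn and excluded from quantitative contracts)."""
    if k < 2:
        raise DimredError("UMAP needs at least 2 components")
    if k > model.n_components:
        raise DimredError(f"k={k} exceeds available components ({model.n_components})")
    import umap  # deferred: optional extra

    emb = umap.UMAP(n_components=2, random_state=seed).fit_transform(
        model.scores.iloc[:, :k].to_numpy())
    return pd.DataFrame(emb, index=model.scores.index, columns=["D1", "D2"])
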