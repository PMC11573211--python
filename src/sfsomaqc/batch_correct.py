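"""Bimodal-status classification (1-D Gaussian mixture on PC2) and
parametric empirical-Bayes batch correction (ComBat).

A laboratory processing artefact leaves many SOMAmers in either a "high" or
a "low" intensity state per sample; on the log-abundance PCA it shows up as
a bimodal second principal component.  Samples are classified into the two
states with a two-component Gaussian mixture fitted to the PC2 scores by
EM, and the state — together with plate — is then removed by ComBat, which
shrinks per-(batch, feature) location and scale estimates toward
batch-level priors (normal for locations, inverse-gamma for scales) before
removing them.

The ComBat implementation follows the standard parametric procedure exactly
(batch-size-weighted grand mean, pooled variance with an n denominator,
method-of-moments priors, iterative conditional updates to tolerance 1e-4)
so that its output is exchangeable with the reference R implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import SomaDataset


class BatchCorrectError(ValueError):
    pass


# --------------------------------------------------------------------------
# 1-D two-component Gaussian mixture


@dataclass
class BimodalAssignment:
    """Per-sample high/low status with the mixture fit behind it."""

    status: pd.Series                 # sample_id -> "high" | "low"
    posterior: pd.Series              # posterior prob of the assigned status
    means: tuple[float, float]        # (low, high); high has the larger mean
    variances: tuple[float, float]
    weight_high: float
    converged: bool
    log_likelihood: float
    seed: int
    ties: list[str] = field(default_factory=list)


def _em_1d(x: np.ndarray, mu: np.ndarray, var: np.ndarray, w: float,
           tol: float = 1e-8, max_iter: int = 500
           ) -> tuple[np.ndarray, np.ndarray, float, float, bool]:
    n = x.size
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        # E-step
        comp = np.empty((n, 2))
        for k in range(2):
            comp[:, k] = np.exp(-0.5 * (x - mu[k]) ** 2 / var[k]) / np.sqrt(2 * np.pi * var[k])
        comp[:, 0] *= (1 - w)
        comp[:, 1] *= w
        tot = comp.sum(axis=1)
        tot = np.where(tot <= 0, np.finfo(float).tiny, tot)
        resp = comp / tot[:, None]
        ll = float(np.log(tot).sum())
        if abs(ll - ll_old) < tol:
            converged = True
            ll_old = ll
            break
        ll_old = ll
        # M-step
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            break
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        var = np.maximum(var, 1e-12)
        w = nk[1] / n
    return mu, var, w, ll_old, converged


def fit_pc2_gmm(pc2_scores: pd.Series | np.ndarray, seed: int = 0,
                n_restarts: int = 5) -> BimodalAssignment:
    """Two-component 1-D Gaussian mixture on PC2 scores, fitted by EM.

    Initialised at the 25th/75th percentiles (restarts jitter the init);
    distinct variances and a free mixing weight; convergence when the
    log-likelihood change falls below 1e-8 or after 500 iterations.
    Assignment is by maximum posterior; exact ties go to the lower-mean
    component and are flagged.
    """
    if isinstance(pc2_scores, pd.Series):
        index = pd.Index(pc2_scores.index.astype(str))
        x = pc2_scores.to_numpy(dtype=float)
    else:
        x = np.asarray(pc2_scores, dtype=float)
        index = pd.Index([str(i) for i in range(x.size)])
    if x.size < 10:
        raise BatchCorrectError("GMM needs at least 10 samples")
    if not np.all(np.isfinite(x)):
        raise BatchCorrectError("non-finite PC2 scores")

    if np.ptp(x) == 0:
        import warnings
        warnings.warn("all PC2 scores identical: degenerate GMM, posteriors 0.5")
        status = pd.Series("low", index=index)
        post = pd.Series(0.5, index=index)
        v = max(float(np.var(x)), 1e-12)
        return BimodalAssignment(status=status, posterior=post,
                                 means=(float(x[0]), float(x[0])),
                                 variances=(v, v), weight_high=0.5,
                                 converged=False, log_likelihood=float("nan"),
                                 seed=seed, ties=list(index))

    rng = np.random.default_rng(seed)
    q25, q75 = np.percentile(x, [25, 75])
    spread = max(float(np.std(x)), 1e-6)
    best = None
    for r in range(max(1, n_restarts)):
        if r == 0:
            mu0 = np.array([q25, q75], dtype=float)
        else:
            mu0 = np.array([q25, q75]) + rng.normal(0, 0.25 * spread, 2)
        if mu0[0] == mu0[1]:
            mu0[1] += 1e-6
        var0 = np.array([spread ** 2, spread ** 2]) / 4.0
        fit = _em_1d(x, mu0.copy(), var0.copy(), 0.5)
        if best is None or fit[3] > best[3]:
            best = fit
    mu, var, w, ll, converged = best

    # orient: component 1 = "high" (larger mean)
    if mu[0] > mu[1]:
        mu, var = mu[::-1].copy(), var[::-1].copy()
        w = 1 - w
    comp = np.empty((x.size, 2))
    for k in range(2):
        comp[:, k] = np.exp(-0.5 * (x - mu[k]) ** 2 / var[k]) / np.sqrt(2 * np.pi * var[k])
    comp[:, 0] *= (1 - w)
    comp[:, 1] *= w
    p_high = comp[:, 1] / comp.sum(axis=1)
    ties = np.isclose(p_high, 0.5, rtol=0, atol=0)
    assign_high = p_high > 0.5          # exact ties -> lower-mean component
    status = pd.Series(np.where(assign_high, "high", "low"), index=index)
    post = pd.Series(np.where(assign_high, p_high, 1 - p_high), index=index)
    return BimodalAssignment(
        status=status, posterior=post,
        means=(float(mu[0]), float(mu[1])),
        variances=(float(var[0]), float(var[1])),
        weight_high=float(w), converged=bool(converged),
        log_likelihood=float(ll), seed=seed,
        ties=list(index[ties]))


# --------------------------------------------------------------------------
# ComBat


@dataclass
class CombatModel:
    """Fitted empirical-Bayes batch model."""

    batches: list[str]
    alpha: np.ndarray                 # per-feature grand mean
    beta: np.ndarray | None           # covariate coefficients (features x q)
    sigma2: np.ndarray                # pooled per-feature variance
    gamma_hat: pd.DataFrame           # unshrunk batch locations (batch x feature)
    gamma_star: pd.DataFrame
    delta2_star: pd.DataFrame
    priors: pd.DataFrame              # per batch: gamma_bar, tau2, a_prior, b_prior
    iterations: dict[str, int]


def _moment_priors(delta_hat: np.ndarray) -> tuple[float, float]:
    m = float(np.mean(delta_hat))
    s2 = float(np.var(delta_hat, ddof=1))
    a = (2 * s2 + m ** 2) / s2
    b = (m * s2 + m ** 3) / s2
    return a, b


def _eb_fit(z: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
            g_bar: float, t2: float, a: float, b: float,
            conv: float = 1e-4) -> tuple[np.ndarray, np.ndarray, int]:
    """Iterative conditional updates for one batch.  z: samples x features."""
    n = z.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    count = 0
    while True:
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((z - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        # signed denominator for the location ratio mirrors the reference
        # implementation's stopping rule exactly (iteration counts must match
        # for bit-level agreement); zero denominators fall back to absolute change
        with np.errstate(divide="ignore", invalid="ignore"):
            g_ratio = np.abs(g_new - g_old) / g_old
        g_ratio = np.where(g_old == 0, np.abs(g_new - g_old), g_ratio)
        change = max(np.max(g_ratio), np.max(np.abs(d_new - d_old) / d_old))
        g_old, d_old = g_new, d_new
        count += 1
        if change < conv:
            break
    return g_old, d_old, count


def combat(dataset: SomaDataset, batch: pd.Series | Sequence[str],
           design: pd.DataFrame | None = None
           ) -> tuple[SomaDataset, CombatModel]:
    """Parametric empirical-Bayes batch correction of a log-scale dataset.

    ``batch`` gives one label per sample (aligned positionally or by
    sample_id index).  ``design`` optionally protects continuous covariates:
    their fitted effects are kept in the data while batch effects are
    removed.  A single batch is an identity (nothing to correct).
    """
    if dataset.scale_state not in ("log", "adjusted"):
        raise BatchCorrectError("ComBat operates on log-scale data")
    sample_ids = dataset.sample_ids
    if isinstance(batch, pd.Series) and set(sample_ids) <= set(map(str, batch.index)):
        labels = batch.loc[sample_ids].astype(str).to_numpy()
    else:
        labels = np.asarray(pd.Series(batch).astype(str))
        if labels.size != len(sample_ids):
            raise BatchCorrectError("batch labels do not align with samples")
    uniq = sorted(set(labels))
    counts = {b: int((labels == b).sum()) for b in uniq}
    singles = [b for b, c in counts.items() if c < 2]
    if singles:
        raise BatchCorrectError(f"batches with a single sample: {singles}")

    out = dataset.copy()
    if len(uniq) == 1:
        out.log_op("combat", batches=uniq, note="single batch: identity")
        n_feat = out.rfu.shape[1]
        model = CombatModel(batches=uniq, alpha=out.values.mean(axis=0), beta=None,
                            sigma2=out.values.var(axis=0),
                            gamma_hat=pd.DataFrame(0.0, index=uniq, columns=out.seq_ids),
                            gamma_star=pd.DataFrame(0.0, index=uniq, columns=out.seq_ids),
                            delta2_star=pd.DataFrame(1.0, index=uniq, columns=out.seq_ids),
                            priors=pd.DataFrame(index=uniq), iterations={})
        return out, model

    y = dataset.values                             # samples x features
    n, n_feat = y.shape
    batch_mod = np.stack([(labels == b).astype(float) for b in uniq], axis=1)
    if design is not None and design.shape[1] > 0:
        x_cov = design.to_numpy(dtype=float)
        if x_cov.shape[0] != n:
            raise BatchCorrectError("design rows do not match samples")
        full = np.hstack([batch_mod, x_cov])
        if np.linalg.matrix_rank(full) < full.shape[1]:
            raise BatchCorrectError("design confounded with batch (rank-deficient)")
    else:
        x_cov = None
        full = batch_mod

    b_hat, *_ = np.linalg.lstsq(full, y, rcond=None)   # (n_batch + q) x features
    n_sizes = np.array([counts[b] for b in uniq], dtype=float)
    grand_mean = (n_sizes / n) @ b_hat[: len(uniq)]
    resid = y - full @ b_hat
    var_pooled = (resid ** 2).sum(axis=0) / n          # n denominator, as reference
    if np.any(var_pooled <= 0):
        raise BatchCorrectError("zero pooled variance for some features")
    stand_mean = np.tile(grand_mean, (n, 1))
    if x_cov is not None:
        stand_mean = stand_mean + x_cov @ b_hat[len(uniq):]
    sd = np.sqrt(var_pooled)
    z = (y - stand_mean) / sd[None, :]

    gamma_hat = np.empty((len(uniq), n_feat))
    delta_hat = np.empty((len(uniq), n_feat))
    for i, b in enumerate(uniq):
        zb = z[labels == b]
        gamma_hat[i] = zb.mean(axis=0)
        delta_hat[i] = zb.var(axis=0, ddof=1)

    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    priors_rows = []
    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    iterations = {}
    for i, b in enumerate(uniq):
        a_p, b_p = _moment_priors(delta_hat[i])
        g, d, it = _eb_fit(z[labels == b], gamma_hat[i], delta_hat[i],
                           gamma_bar[i], tau2[i], a_p, b_p)
        gamma_star[i], delta_star[i] = g, d
        iterations[b] = it
        priors_rows.append({"batch": b, "gamma_bar": gamma_bar[i], "tau2": tau2[i],
                            "a_prior": a_p, "b_prior": b_p})

    z_adj = z.copy()
    for i, b in enumerate(uniq):
        rows = labels == b
        z_adj[rows] = (z[rows] - gamma_star[i][None, :]) / np.sqrt(delta_star[i])[None, :]
    corrected = z_adj * sd[None, :] + stand_mean

    out.rfu = pd.DataFrame(corrected, index=dataset.rfu.index, columns=dataset.rfu.columns)
    out.log_op("combat", batches=uniq)
    seqs = dataset.seq_ids
    model = CombatModel(
        batches=uniq, alpha=grand_mean,
        beta=None if x_cov is None else b_hat[len(uniq):],
        sigma2=var_pooled,
        gamma_hat=pd.DataFrame(gamma_hat, index=uniq, columns=seqs),
        gamma_star=pd.DataFrame(gamma_star, index=uniq, columns=seqs),
        delta2_star=pd.DataFrame(delta_star, index=uniq, columns=seqs),
        priors=pd.DataFrame(priors_rows).set_index("batch"),
        iterations=iterations)
    return out, model


def correct_bimodal_and_plate(dataset: SomaDataset,
                              assignment: BimodalAssignment,
                              order: tuple[str, str] = ("bimodal", "plate"),
                              interaction: bool = False
                              ) -> tuple[SomaDataset, dict[str, CombatModel]]:
    """Remove the bimodal-status and plate batch effects.

    By default two sequential ComBat passes (status, then plate); with
    ``interaction=True`` a single pass on the status x plate factor.

    Correction applies to the samples the assignment covers (the study +
    pooled analysis set); assay-control wells are dropped from the output.
    """
    assigned = set(map(str, assignment.status.index))
    keep = [s for s in dataset.sample_ids if s in assigned]
    if len(keep) < len(dataset.samples):
        dataset = dataset.subset(sample_ids=keep)
    plate = dataset.samples["plate_id"].astype(str)
    if plate.isna().any() or (plate == "").any():
        raise BatchCorrectError("plate labels missing")
    status = assignment.status.loc[dataset.sample_ids].astype(str)
    models: dict[str, CombatModel] = {}
    if interaction:
        combo = status.to_numpy() + ":" + plate.to_numpy()
        out, models["bimodal_x_plate"] = combat(dataset, pd.Series(combo))
        return out, models
    out = dataset
    for which in order:
        labels = status.to_numpy() if which == "bimodal" else plate.to_numpy()
        out, models[which] = combat(out, pd.Series(labels))
    return out, models
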