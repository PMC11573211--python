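"""Standardisation of raw RFU: the vendor-style normalisation ladder.

Four steps operate on the linear scale, in order:

i)   **hybridisation control normalisation** — per-well scale factors from
     spiked-in hybridisation-control SOMAmers, removing well-to-well
     readout-efficiency variation;
ii)  **plate scaling** — one factor per plate from the plasma calibrator
     wells, removing overall between-plate intensity differences;
iii) **median signal normalisation** — per-(sample, dilution-bin) factors
     equalising total signal across samples.  Implemented but *excluded*
     from the default ladder: on synovial fluid, total-signal differences
     carry real biology and median normalisation degrades both
     repeatability and concordance with orthogonal immunoassays;
iv)  **calibration** — per-(plate, SOMAmer) factors pinning each plate's
     calibrator median to the reagent's reference value.

All factors are strictly positive, are returned alongside the transformed
dataset, and suffice to reproduce the standardised data from raw input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import SomaDataset

DEFAULT_STEPS = ("hybridisation", "plate_scale", "calibrate")
STEP_NAMES = ("hybridisation", "plate_scale", "median", "calibrate")


class StandardisationError(ValueError):
    pass


@dataclass
class NormalisationFactors:
    """Multiplicative factors recorded by the standardisation ladder."""

    well_factors: pd.Series | None = None            # per sample_id
    plate_factors: pd.Series | None = None           # per plate_id
    calibration_factors: pd.DataFrame | None = None  # plate_id x seq_id
    median_factors: pd.DataFrame | None = None       # sample_id x dilution bin
    steps: list[str] = field(default_factory=list)

    def check_positive(self) -> None:
        for name in ("well_factors", "plate_factors"):
            s = getattr(self, name)
            if s is not None and not np.all(np.isfinite(s) & (s > 0)):
                raise StandardisationError(f"{name} contains non-positive factors")

    def apply(self, dataset: SomaDataset) -> SomaDataset:
        """Re-apply the stored factors to a raw dataset (reproducibility check)."""
        out = dataset.copy()
        values = out.values
        sample_ids = out.sample_ids
        plate = out.samples["plate_id"].astype(str)
        for step in self.steps:
            if step == "hybridisation":
                values = values * self.well_factors.loc[sample_ids].to_numpy()[:, None]
            elif step == "plate_scale":
                values = values * self.plate_factors.loc[plate].to_numpy()[:, None]
            elif step == "calibrate":
                values = values * self.calibration_factors.loc[plate].to_numpy()
            elif step == "median":
                bins = out.somamers["dilution_bin"].to_numpy()
                f = self.median_factors.loc[sample_ids]
                for b in f.columns:
                    values[:, bins == b] *= f[b].to_numpy()[:, None]
        out.rfu = pd.DataFrame(values, index=out.rfu.index, columns=out.rfu.columns)
        out.scale_state = "standardised"
        return out


def hybridisation_normalise(dataset: SomaDataset
                            ) -> tuple[SomaDataset, pd.Series]:
    """Per-well hybridisation-control normalisation.

    For each plate, the reference for control *h* is the median of its RFU
    over the plate's wells; each well's factor is the median over controls
    of (reference / observed), and all values in the well are multiplied by
    it.  By construction the per-well median of (reference / RFU) is 1
    afterwards.
    """
    hyb_mask = dataset.somamers["is_hyb_control"].fillna(False).astype(bool).to_numpy()
    if hyb_mask.sum() < 1:
        raise StandardisationError("dataset has no hybridisation-control SOMAmers")
    values = dataset.values
    plate = dataset.samples["plate_id"].astype(str).to_numpy()
    sample_ids = dataset.sample_ids
    factors = np.empty(len(sample_ids))
    for q in pd.unique(plate):
        rows = np.nonzero(plate == q)[0]
        ctrl = values[np.ix_(rows, np.nonzero(hyb_mask)[0])]
        if np.any(ctrl <= 0):
            bad = rows[np.nonzero(np.any(ctrl <= 0, axis=1))[0][0]]
            well = dataset.samples["well"].iloc[bad]
            raise StandardisationError(
                f"non-positive hybridisation-control RFU in well {well} on plate {q}")
        ref = np.median(ctrl, axis=0)                       # per control
        ratios = ref[None, :] / ctrl                        # wells x controls
        factors[rows] = np.median(ratios, axis=1)
    out = dataset.with_values(values * factors[:, None])
    out.log_op("hybridisation_normalise", n_controls=int(hyb_mask.sum()))
    return out, pd.Series(factors, index=sample_ids, name="well_factor")


def _calibrator_refs(dataset: SomaDataset) -> tuple[np.ndarray, np.ndarray]:
    """(protein-with-reference mask, reference values).  Falls back to the
    across-plate median of plate calibrator medians when the annotation
    carries no reference (single-run self-reference)."""
    refs = dataset.somamers["calibrator_reference"].to_numpy(dtype=float)
    prot = dataset.protein_mask()
    have = prot & np.isfinite(refs) & (refs > 0)
    if not have.any():
        cal = dataset.role_mask("calibrator")
        if not cal.any():
            raise StandardisationError("no calibrator wells and no reference values")
        plate = dataset.samples["plate_id"].astype(str).to_numpy()
        values = dataset.values
        per_plate = [np.median(values[cal & (plate == q)], axis=0)
                     for q in pd.unique(plate[cal])]
        refs = np.median(np.vstack(per_plate), axis=0)
        have = prot & np.isfinite(refs) & (refs > 0)
    return have, refs


def plate_scale(dataset: SomaDataset) -> tuple[SomaDataset, pd.Series]:
    """One multiplicative factor per plate from the plasma calibrator wells:
    SF_q = median over SOMAmers of (reference / plate calibrator median)."""
    values = dataset.values
    plate = dataset.samples["plate_id"].astype(str).to_numpy()
    cal = dataset.role_mask("calibrator")
    have, refs = _calibrator_refs(dataset)
    plates = pd.unique(plate)
    sf = {}
    for q in plates:
        rows = cal & (plate == q)
        if not rows.any():
            raise StandardisationError(f"plate {q} has no calibrator wells")
        m = np.median(values[rows][:, have], axis=0)
        sf[q] = float(np.median(refs[have] / m))
    factors = pd.Series(sf, name="plate_factor")
    scaled = values * factors.loc[plate].to_numpy()[:, None]
    out = dataset.with_values(scaled)
    out.log_op("plate_scale", plates=len(plates))
    return out, factors


def calibrate(dataset: SomaDataset) -> tuple[SomaDataset, pd.DataFrame]:
    """Per-(plate, SOMAmer) calibration pinning calibrator medians to the
    references.  Afterwards every plate's calibrator median equals the
    reference exactly for each calibrated SOMAmer."""
    values = dataset.values
    plate = dataset.samples["plate_id"].astype(str).to_numpy()
    cal = dataset.role_mask("calibrator")
    have, refs = _calibrator_refs(dataset)
    plates = pd.unique(plate)
    fac = pd.DataFrame(1.0, index=plates, columns=dataset.seq_ids)
    for q in plates:
        rows = cal & (plate == q)
        if not rows.any():
            raise StandardisationError(f"plate {q} has no calibrator wells")
        m = np.median(values[rows], axis=0)
        zero = have & (m <= 0)
        if zero.any():
            sid = dataset.seq_ids[np.nonzero(zero)[0][0]]
            raise StandardisationError(
                f"zero calibrator median for SOMAmer {sid} on plate {q}")
        col = np.ones_like(m)
        col[have] = refs[have] / m[have]
        fac.loc[q] = col
    scaled = values * fac.loc[plate].to_numpy()
    out = dataset.with_values(scaled)
    out.log_op("calibrate", plates=len(plates))
    return out, fac


def median_normalise(dataset: SomaDataset) -> tuple[SomaDataset, pd.DataFrame]:
    """Median signal normalisation within dilution bins.

    Within each bin, each sample's values are divided by the sample's median
    ratio to the per-SOMAmer cohort median.  Factors are computed separately
    within sample-role groups (study + pooled vs calibrator-type wells) so
    plasma controls do not drive participant factors.
    """
    values = dataset.values.copy()
    bins = dataset.somamers["dilution_bin"].to_numpy(dtype=float)
    sample_ids = dataset.sample_ids
    study_like = dataset.role_mask("study", "pooled_oa", "pooled_injury")
    groups = [study_like, ~study_like]
    uniq_bins = [b for b in pd.unique(bins) if np.isfinite(b)]
    factors = pd.DataFrame(1.0, index=sample_ids, columns=uniq_bins)
    for g in groups:
        if not g.any():
            continue
        for b in uniq_bins:
            cols = bins == b
            if cols.sum() < 2:
                raise StandardisationError(
                    f"dilution bin {b} has fewer than 2 SOMAmers")
            block = values[np.ix_(g, np.nonzero(cols)[0])]
            med = np.median(block, axis=0)
            ratios = block / med[None, :]
            f = 1.0 / np.median(ratios, axis=1)
            values[np.ix_(g, np.nonzero(cols)[0])] = block * f[:, None]
            factors.loc[sample_ids[g], b] = f
    out = dataset.with_values(values)
    out.log_op("median_normalise", bins=[float(b) for b in uniq_bins])
    return out, factors


def run_standardisation(dataset: SomaDataset,
                        steps: tuple[str, ...] | list[str] = DEFAULT_STEPS
                        ) -> tuple[SomaDataset, NormalisationFactors]:
    """Apply standardisation steps in order and mark the result standardised.

    The default ladder is hybridisation -> plate scaling -> calibration;
    ``median`` may be inserted explicitly to reproduce the full vendor
    ladder for comparison.
    """
    if dataset.scale_state != "raw":
        raise StandardisationError(
            f"standardisation expects raw data, got {dataset.scale_state!r}")
    if len(set(steps)) != len(steps):
        raise StandardisationError(f"repeated step in {steps}")
    unknown = [s for s in steps if s not in STEP_NAMES]
    if unknown:
        raise StandardisationError(f"unknown steps {unknown}; choose from {STEP_NAMES}")
    out = dataset
    factors = NormalisationFactors(steps=list(steps))
    for step in steps:
        if step == "hybridisation":
            out, factors.well_factors = hybridisation_normalise(out)
        elif step == "plate_scale":
            out, factors.plate_factors = plate_scale(out)
        elif step == "calibrate":
            out, factors.calibration_factors = calibrate(out)
        elif step == "median":
            out, factors.median_factors = median_normalise(out)
    factors.check_positive()
    out.scale_state = "standardised"
    out.log_op("run_standardisation", steps=list(steps))
    return out, factors


def dilution_adjusted_abundance(dataset: SomaDataset) -> pd.Series:
    """Per-SOMAmer abundance: median study-sample RFU divided by the
    SOMAmer's dilution-bin fraction (diagnostic axis only)."""
    study = dataset.study_mask()
    med = np.median(dataset.values[study], axis=0)
    bins = dataset.somamers["dilution_bin"].to_numpy(dtype=float)
    return pd.Series(med / bins, index=dataset.seq_ids, name="abundance")


def log_transform(dataset: SomaDataset, base: float | None = None) -> SomaDataset:
    """Elementwise logarithm (natural by default).  Values must be positive."""
    values = dataset.values
    bad = ~(values > 0)
    if bad.any():
        i, j = next(zip(*np.nonzero(bad)))
        raise StandardisationError(
            f"non-positive value at sample {dataset.sample_ids[i]}, "
            f"SOMAmer {dataset.seq_ids[j]}: cannot log-transform")
    logged = np.log(values)
    if base is not None:
        logged = logged / np.log(base)
    out = dataset.with_values(logged, scale_state="log")
    out.log_op("log_transform", base=base or "e")
    return out


def exp_transform(dataset: SomaDataset, base: float | None = None) -> SomaDataset:
    """Inverse of :func:`log_transform`."""
    values = dataset.values
    if base is not None:
        values = values * np.log(base)
    out = dataset.with_values(np.exp(values), scale_state="standardised")
    out.log_op("exp_transform", base=base or "e")
    return out
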