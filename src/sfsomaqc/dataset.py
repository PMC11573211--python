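"""Core in-memory container for an aptamer-proteomics run.

A :class:`SomaDataset` bundles the RFU (relative fluorescence unit) matrix
with its two annotation tables — one row per SOMAmer reagent, one row per
sample well — plus an append-only provenance log of the transforms that have
been applied.  All pipeline stages accept and return this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable

import numpy as np
import pandas as pd

#: Permitted assay dilution fractions ("dilution bins").
DILUTION_BINS = (0.20, 0.005, 0.00005)

#: SOMAmer reagent categories.  Everything except ``protein`` is a control
#: or retired reagent and is removed by the control filter.
SOMAMER_TYPES = (
    "protein",
    "spuriomer",
    "hyb_control_elution",
    "deprecated",
    "non_biotin",
    "non_cleavable",
)

SECRETION_CLASSES = ("secreted", "nuclear_not_secreted", "not_secreted_other", "unknown")

SAMPLE_ROLES = ("study", "pooled_oa", "pooled_injury", "calibrator", "plasma_qc", "blank")

DISEASE_GROUPS = ("oa", "injury", "healthy", "inflammatory", "none")

SCALE_STATES = ("raw", "standardised", "log", "adjusted")

#: Columns of the SOMAmer annotation table, with pandas dtypes.
SOMAMER_COLUMNS = {
    "seq_id": "string",
    "target_name": "string",
    "dilution_bin": "float64",
    "organism": "string",
    "somamer_type": "string",
    "secretion_class": "string",
    "calibrator_reference": "float64",
    "is_hyb_control": "bool",
}

#: Columns of the sample annotation table.
SAMPLE_COLUMNS = {
    "sample_id": "string",
    "participant_id": "string",
    "role": "string",
    "plate_id": "string",
    "well": "string",
    "processing_batch": "Int64",
    "processing_order": "Int64",
    "cohort": "string",
    "disease_group": "string",
    "spun": "boolean",
    "blood_grade": "Int64",
    "volume_ml": "float64",
    "sample_age_years": "float64",
    "freeze_thaw_count": "Int64",
    "vendor_flag": "boolean",
}

WELL_ROWS = "ABCDEFGH"
WELL_COLS = range(1, 13)
ALL_WELLS = tuple(f"{r}{c}" for r in WELL_ROWS for c in WELL_COLS)


def well_sort_key(well: str) -> tuple[int, int]:
    """Row-major (A1, A2, ..., H12) ordering key for a well label."""
    return (WELL_ROWS.index(well[0]), int(well[1:]))


@dataclass
class SomaDataset:
    """RFU matrix plus SOMAmer and sample annotations and a provenance log.

    Parameters
    ----------
    rfu
        samples x SOMAmers DataFrame.  Index aligns with
        ``samples['sample_id']`` and columns with ``somamers['seq_id']``.
    somamers, samples
        Annotation tables (see :data:`SOMAMER_COLUMNS`, :data:`SAMPLE_COLUMNS`).
    scale_state
        One of :data:`SCALE_STATES`.
    provenance
        Append-only list of ``(operation, parameters)`` records.
    """

    rfu: pd.DataFrame
    somamers: pd.DataFrame
    samples: pd.DataFrame
    scale_state: str = "raw"
    provenance: list[tuple[str, dict[str, Any]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.scale_state not in SCALE_STATES:
            raise ValueError(f"unknown scale_state {self.scale_state!r}")
        n_s, n_p = self.rfu.shape
        if n_s != len(self.samples) or n_p != len(self.somamers):
            raise ValueError(
                f"matrix shape {self.rfu.shape} does not match annotation "
                f"lengths ({len(self.samples)} samples, {len(self.somamers)} SOMAmers)"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def seq_ids(self) -> pd.Index:
        return pd.Index(self.somamers["seq_id"].astype(str))

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.samples["sample_id"].astype(str))

    @property
    def values(self) -> np.ndarray:
        return self.rfu.to_numpy(dtype=float)

    def role_mask(self, *roles: str) -> np.ndarray:
        return self.samples["role"].isin(roles).to_numpy()

    def study_mask(self, include_pooled: bool = False) -> np.ndarray:
        """Boolean mask over samples for study wells (optionally + pooled)."""
        roles = ["study"]
        if include_pooled:
            roles += ["pooled_oa", "pooled_injury"]
        return self.role_mask(*roles)

    def protein_mask(self) -> np.ndarray:
        """Mask over SOMAmers for human protein reagents (non-control)."""
        ann = self.somamers
        return ((ann["somamer_type"] == "protein")
                & (ann["organism"].str.lower() == "human")).to_numpy()

    def log_op(self, name: str, **params: Any) -> None:
        """Append an operation record to the provenance log."""
        self.provenance.append((name, params))

    def copy(self) -> "SomaDataset":
        return SomaDataset(
            rfu=self.rfu.copy(),
            somamers=self.somamers.copy(),
            samples=self.samples.copy(),
            scale_state=self.scale_state,
            provenance=list(self.provenance),
        )

    def with_values(self, values: np.ndarray, scale_state: str | None = None) -> "SomaDataset":
        """Return a copy with the matrix replaced (annotations shared by copy)."""
        out = self.copy()
        out.rfu = pd.DataFrame(values, index=self.rfu.index, columns=self.rfu.columns)
        if scale_state is not None:
            out.scale_state = scale_state
        return out

    def subset(self, sample_ids: Iterable[str] | None = None,
               seq_ids: Iterable[str] | None = None) -> "SomaDataset":
        """Subset by sample and/or SOMAmer identifier, preserving order."""
        out = self.copy()
        if sample_ids is not None:
            keep = set(map(str, sample_ids))
            mask = out.samples["sample_id"].astype(str).isin(keep).to_numpy()
            out.samples = out.samples.loc[mask].reset_index(drop=True)
            out.rfu = out.rfu.loc[mask].reset_index(drop=True)
        if seq_ids is not None:
            keep = set(map(str, seq_ids))
            pmask = out.somamers["seq_id"].astype(str).isin(keep).to_numpy()
            out.somamers = out.somamers.loc[pmask].reset_index(drop=True)
            out.rfu = out.rfu.iloc[:, pmask.nonzero()[0]]
        return out


def empty_somamer_table(n: int = 0) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series([None] * n, dtype=t) for c, t in SOMAMER_COLUMNS.items()})


def empty_sample_table(n: int = 0) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series([None] * n, dtype=t) for c, t in SAMPLE_COLUMNS.items()})
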