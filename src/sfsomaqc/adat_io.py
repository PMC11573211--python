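"""Reading, writing and validation of ADAT-style tab-delimited files.

The dialect is deliberately minimal and fully round-trippable:

.. code-block:: text

    ^HEADER
    !AdatVersion<TAB>1.0
    !ScaleState<TAB>raw
    !Provenance<TAB><JSON list of [operation, params]>
    !AnyOtherKey<TAB>preserved verbatim
    ^COL_DATA
    <SOMAmer annotation table, TSV with header row>
    ^ROW_DATA_AND_TABLE
    <header: sample annotation columns ... then one column per seq_id>
    <one row per sample: annotations then RFU values>

Vendor files whose column names differ map onto the canonical schema via an
alias table (``{canonical_name: file_name}``), loadable from YAML or JSON.
Missing metadata is encoded as an empty field and surfaced as missing, never
as zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .dataset import (
    DILUTION_BINS,
    SAMPLE_COLUMNS,
    SOMAMER_COLUMNS,
    SomaDataset,
)

_HEADER = "^HEADER"
_COL_DATA = "^COL_DATA"
_TABLE = "^ROW_DATA_AND_TABLE"


class AdatFormatError(ValueError):
    """Raised when a file does not parse as the ADAT dialect."""


class AdatValidationError(ValueError):
    """Raised when a parsed file violates dataset invariants."""


def load_alias_map(path: str | Path) -> dict[str, str]:
    """Load a ``{canonical: file_field}`` alias table from YAML or JSON."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise AdatFormatError(f"alias map {path} must be a mapping")
    return {str(k): str(v) for k, v in data.items()}


def _format_value(v: Any) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v is pd.NA:
        return ""
    if isinstance(v, (bool, np.bool_)):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _parse_table(lines: list[str], start_line: int) -> pd.DataFrame:
    header = lines[0].split("\t")
    rows = [ln.split("\t") for ln in lines[1:]]
    for i, r in enumerate(rows):
        if len(r) != len(header):
            raise AdatFormatError(
                f"line {start_line + 1 + i}: expected {len(header)} fields, got {len(r)}"
            )
    return pd.DataFrame(rows, columns=header)


def _coerce(df: pd.DataFrame, schema: Mapping[str, str]) -> pd.DataFrame:
    out = {}
    for col, dtype in schema.items():
        if col not in df.columns:
            out[col] = pd.Series([pd.NA] * len(df), dtype=dtype)
            continue
        s = df[col].replace("", pd.NA)
        if dtype in ("bool", "boolean"):
            s = s.map({"true": True, "false": False, None: pd.NA}, na_action="ignore")
            out[col] = s.astype("boolean" if dtype == "boolean" else bool)
        elif dtype in ("float64",):
            out[col] = pd.to_numeric(s, errors="raise").astype("float64")
        elif dtype == "Int64":
            out[col] = pd.to_numeric(s, errors="raise").astype("Int64")
        else:
            out[col] = s.astype("string")
    return pd.DataFrame(out)


def write_adat(dataset: SomaDataset, path: str | Path,
               alias_map: Mapping[str, str] | None = None) -> None:
    """Write *dataset* to *path* in the ADAT dialect.

    ``read_adat`` is an exact inverse on annotations and RFU (floats are
    emitted with shortest-round-trip ``repr``).
    """
    alias = dict(alias_map or {})

    def a(name: str) -> str:
        return alias.get(name, name)

    lines: list[str] = [_HEADER]
    lines.append("!AdatVersion\t1.0")
    lines.append(f"!ScaleState\t{dataset.scale_state}")
    lines.append("!Provenance\t" + json.dumps([[n, p] for n, p in dataset.provenance]))

    lines.append(_COL_DATA)
    som_cols = list(SOMAMER_COLUMNS)
    lines.append("\t".join(a(c) for c in som_cols))
    for _, row in dataset.somamers.iterrows():
        lines.append("\t".join(_format_value(row.get(c)) for c in som_cols))

    lines.append(_TABLE)
    sam_cols = list(SAMPLE_COLUMNS)
    seq_ids = dataset.seq_ids.tolist()
    lines.append("\t".join([a(c) for c in sam_cols] + seq_ids))
    values = dataset.values
    for i, (_, row) in enumerate(dataset.samples.iterrows()):
        fields = [_format_value(row.get(c)) for c in sam_cols]
        fields += [repr(float(v)) for v in values[i]]
        lines.append("\t".join(fields))

    Path(path).write_text("\n".join(lines) + "\n")


def read_adat(path: str | Path,
              alias_map: Mapping[str, str] | None = None) -> SomaDataset:
    """Read an ADAT-dialect file into a :class:`SomaDataset`.

    Raises :class:`AdatFormatError` on malformed structure (naming the first
    offending line) and :class:`AdatValidationError` on duplicate ``seq_id``
    or duplicate ``(plate, well)`` assignments.
    """
    alias = dict(alias_map or {})
    rev = {v: k for k, v in alias.items()}

    raw_lines = Path(path).read_text().splitlines()
    sections: dict[str, tuple[int, list[str]]] = {}
    current: str | None = None
    for lineno, ln in enumerate(raw_lines, start=1):
        if ln.startswith("^"):
            if ln not in (_HEADER, _COL_DATA, _TABLE):
                raise AdatFormatError(f"line {lineno}: unknown section marker {ln!r}")
            current = ln
            sections[current] = (lineno, [])
        elif current is None:
            raise AdatFormatError(f"line {lineno}: content before any section marker")
        else:
            sections[current][1].append(ln)

    for required in (_HEADER, _COL_DATA, _TABLE):
        if required not in sections:
            raise AdatFormatError(f"missing {required} block")

    # header key/value block
    scale_state = "raw"
    provenance: list[tuple[str, dict]] = []
    hdr_start, hdr_lines = sections[_HEADER]
    for off, ln in enumerate(hdr_lines):
        if not ln.strip():
            continue
        if not ln.startswith("!") or "\t" not in ln:
            raise AdatFormatError(f"line {hdr_start + 1 + off}: malformed header line {ln!r}")
        key, _, val = ln[1:].partition("\t")
        if key == "ScaleState":
            scale_state = val
        elif key == "Provenance":
            provenance = [(n, p) for n, p in json.loads(val)]

    col_start, col_lines = sections[_COL_DATA]
    col_lines = [ln for ln in col_lines if ln.strip()]
    if not col_lines:
        raise AdatFormatError(f"line {col_start}: empty ^COL_DATA block")
    som_raw = _parse_table(col_lines, col_start)
    som_raw = som_raw.rename(columns=rev)
    somamers = _coerce(som_raw, SOMAMER_COLUMNS)

    tbl_start, tbl_lines = sections[_TABLE]
    tbl_lines = [ln for ln in tbl_lines if ln.strip()]
    if len(tbl_lines) < 1:
        raise AdatFormatError(f"line {tbl_start}: missing matrix block")
    header = tbl_lines[0].split("\t")
    header = [rev.get(h, h) for h in header]
    n_meta = sum(1 for h in header if h in SAMPLE_COLUMNS)
    seq_ids = header[n_meta:]
    expected_ids = somamers["seq_id"].astype(str).tolist()
    if seq_ids != expected_ids:
        raise AdatFormatError(
            f"line {tbl_start + 1}: matrix seq_id columns do not match ^COL_DATA order"
        )
    table = _parse_table(tbl_lines, tbl_start)
    table.columns = header
    samples = _coerce(table.iloc[:, :n_meta], SAMPLE_COLUMNS)
    try:
        rfu_values = table.iloc[:, n_meta:].astype(float)
    except ValueError as exc:
        raise AdatFormatError(f"non-numeric RFU value in matrix block: {exc}") from exc
    rfu = pd.DataFrame(rfu_values.to_numpy(dtype=float), columns=seq_ids)

    dup_seq = somamers["seq_id"][somamers["seq_id"].duplicated(keep=False)].unique().tolist()
    if dup_seq:
        raise AdatValidationError(f"duplicate seq_id values: {sorted(dup_seq)}")
    pw = samples[["plate_id", "well"]].astype(str).agg(":".join, axis=1)
    dup_mask = pw.duplicated(keep=False) & samples["plate_id"].notna() & samples["well"].notna()
    if dup_mask.any():
        dups = samples.loc[dup_mask, "sample_id"].tolist()
        raise AdatValidationError(f"duplicate (plate, well) assignments for samples: {dups}")

    return SomaDataset(rfu=rfu, somamers=somamers, samples=samples,
                       scale_state=scale_state, provenance=provenance)


@dataclass
class ValidationIssue:
    rule: str
    severity: str  # "error" | "warning"
    ids: list[Any]
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def add(self, rule: str, severity: str, ids: list[Any], message: str) -> None:
        self.issues.append(ValidationIssue(rule, severity, list(ids), message))

    def by_rule(self, rule: str) -> list[ValidationIssue]:
        return [i for i in self.issues if i.rule == rule]


def validate_dataset(dataset: SomaDataset) -> ValidationReport:
    """Report-only check of dataset invariants; never mutates its input."""
    report = ValidationReport()
    som, sam = dataset.somamers, dataset.samples

    dup = som["seq_id"][som["seq_id"].duplicated(keep=False)].unique().tolist()
    if dup:
        report.add("unique_seq_id", "error", dup, "duplicate seq_id values")

    pw = sam[["plate_id", "well"]].astype(str).agg(":".join, axis=1)
    dmask = pw.duplicated(keep=False) & sam["plate_id"].notna() & sam["well"].notna()
    if dmask.any():
        report.add("unique_plate_well", "error", sam.loc[dmask, "sample_id"].tolist(),
                   "duplicate (plate, well) assignments")

    bad_bin = ~som["dilution_bin"].isna() & ~som["dilution_bin"].isin(DILUTION_BINS)
    if bad_bin.any():
        report.add("dilution_bin", "error", som.loc[bad_bin, "seq_id"].tolist(),
                   f"dilution_bin outside permitted set {DILUTION_BINS}")

    hyb_bad = som["is_hyb_control"].fillna(False).astype(bool) & \
        (som["somamer_type"] != "hyb_control_elution")
    if hyb_bad.any():
        report.add("hyb_control_type", "error", som.loc[hyb_bad, "seq_id"].tolist(),
                   "is_hyb_control set but somamer_type is not hyb_control_elution")

    ctrl = sam["role"].isin(["blank", "calibrator"])
    bad_dg = ctrl & (sam["disease_group"] != "none")
    if bad_dg.any():
        report.add("control_disease_group", "error", sam.loc[bad_dg, "sample_id"].tolist(),
                   "blanks and calibrators must have disease_group 'none'")

    values = dataset.values
    neg = ~np.isfinite(values) | (values < 0)
    if neg.any():
        cells = [(str(dataset.sample_ids[i]), str(dataset.seq_ids[j]))
                 for i, j in zip(*np.nonzero(neg))]
        report.add("nonnegative_finite_rfu", "error", cells[:100],
                   "negative or non-finite RFU values")

    blanks = sam[sam["role"] == "blank"]
    if len(sam):
        counts = blanks.groupby("plate_id").size()
        for plate in sam["plate_id"].dropna().unique():
            n = int(counts.get(plate, 0))
            if n < 3:
                report.add("blanks_per_plate", "warning", [plate],
                           f"plate {plate} has {n} blanks (<3): LOD computation will fail")
    return report
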