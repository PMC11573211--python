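"""Shared fixtures: synthetic study designs and small hand-built datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sfsomaqc.dataset import SomaDataset, empty_sample_table, empty_somamer_table
from sfsomaqc.pipeline import PipelineConfig, run_pipeline
from sfsomaqc.synthdata import SynthConfig, generate_dataset, generate_paired_spun_unspun

#: fixed seeds defining the deterministic study conditions of the suite
BATTERY_SEED = 7
CLEAN_SEED = 11


def make_dataset(rfu: np.ndarray, *, roles=None, plates=None, wells=None,
                 scale_state: str = "raw", seq_prefix: str = "SL",
                 hyb: int = 0, somamer_types=None, organisms=None,
                 calibrator_reference=None, dilution=None,
                 vendor_flags=None, blood_grades=None) -> SomaDataset:
    """Small hand-built dataset for unit tests."""
    rfu = np.asarray(rfu, dtype=float)
    n, p = rfu.shape
    som = empty_somamer_table(p)
    seq_ids = [f"{seq_prefix}{j + 1:03d}" for j in range(p)]
    som["seq_id"] = pd.array(seq_ids, dtype="string")
    types = somamer_types or (["hyb_control_elution"] * hyb + ["protein"] * (p - hyb))
    som["somamer_type"] = pd.array(types, dtype="string")
    som["is_hyb_control"] = [t == "hyb_control_elution" for t in types]
    som["organism"] = pd.array(organisms or ["human"] * p, dtype="string")
    som["dilution_bin"] = dilution if dilution is not None else [0.005] * p
    if calibrator_reference is not None:
        som["calibrator_reference"] = calibrator_reference
    sam = empty_sample_table(n)
    sam["sample_id"] = pd.array([f"S{i + 1:03d}" for i in range(n)], dtype="string")
    sam["participant_id"] = sam["sample_id"]
    sam["role"] = pd.array(roles or ["study"] * n, dtype="string")
    from sfsomaqc.dataset import ALL_WELLS
    sam["plate_id"] = pd.array(plates or [f"P{i // 96 + 1}" for i in range(n)],
                               dtype="string")
    sam["well"] = pd.array(wells or [ALL_WELLS[i % 96] for i in range(n)],
                           dtype="string")
    sam["disease_group"] = pd.array(
        ["none" if r in ("blank", "calibrator", "plasma_qc") else "oa"
         for r in (roles or ["study"] * n)], dtype="string")
    if vendor_flags is not None:
        sam["vendor_flag"] = pd.array(vendor_flags, dtype="boolean")
    if blood_grades is not None:
        sam["blood_grade"] = pd.array(blood_grades, dtype="Int64")
    return SomaDataset(rfu=pd.DataFrame(rfu, columns=seq_ids), somamers=som,
                       samples=sam, scale_state=scale_state)


@pytest.fixture(scope="session")
def battery():
    """Full 22-plate study design with every planted effect, plus truth."""
    cfg = SynthConfig(seed=BATTERY_SEED)
    dataset, truth = generate_dataset(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def battery_paired(battery):
    cfg, _, _ = battery
    return generate_paired_spun_unspun(cfg, 18)


@pytest.fixture(scope="session")
def battery_run(battery, battery_paired):
    """End-to-end pipeline result on the battery fixture (both branches)."""
    _, dataset, _ = battery
    paired, _ = battery_paired
    return run_pipeline(dataset, paired, PipelineConfig())


@pytest.fixture(scope="session")
def clean4():
    """Clean 4-plate fixture: technical structure, no planted bad entities."""
    cfg = SynthConfig.normalisation_benchmark(CLEAN_SEED)
    dataset, truth = generate_dataset(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def clean4_paired(clean4):
    cfg, _, _ = clean4
    return generate_paired_spun_unspun(cfg, 18)
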