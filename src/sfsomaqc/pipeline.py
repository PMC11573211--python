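"""End-to-end QC pipeline: standardise -> correct -> filter, with manifest.

Stage order (the optimised synovial-fluid pipeline):

1. standardisation on the linear scale (hybridisation, plate scaling,
   calibration; median normalisation deliberately omitted by default);
2. natural log transform;
3. PCA of study+pooled samples; two-component GMM on PC2 -> bimodal status;
4. ComBat for bimodal status, then plate;
5. co-primary branches: without IPS adjustment, and with per-protein IPS
   residualisation (weights frozen from a paired spun/unspun dataset);
6. filter battery per branch (LOD and total-RFU on the standardised linear
   companion, confounder/R²/PCA on the corrected log data);
7. final PCA per branch.

Identical config + inputs give identical outputs; the manifest records
parameters, seeds and per-stage SHA-256 checksums of the data matrix.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .batch_correct import BimodalAssignment, CombatModel, correct_bimodal_and_plate, fit_pc2_gmm
from .dataset import SomaDataset
from .dimred import PcaModel, fit_pca
from .filters import FilterConfig, FilterReport, apply_filters
from .ips import IpsModel, adjust_for_ips, compute_ips, compute_ips_weights
from .standardise import DEFAULT_STEPS, NormalisationFactors, log_transform, run_standardisation


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    standardisation_steps: tuple[str, ...] = DEFAULT_STEPS
    log_base: float | None = None           # None = natural log
    gmm_seed: int = 0
    combat_order: tuple[str, str] = ("bimodal", "plate")
    ips_branch: str = "both"                # both | with_ips | without_ips
    filters: FilterConfig = field(default_factory=FilterConfig)

    def branches(self) -> list[str]:
        if self.ips_branch == "both":
            return ["without_ips", "with_ips"]
        if self.ips_branch in ("with_ips", "without_ips"):
            return [self.ips_branch]
        raise PipelineError(f"unknown ips_branch {self.ips_branch!r}")


@dataclass
class PipelineResult:
    datasets: dict[str, SomaDataset]            # branch -> filtered dataset
    reports: dict[str, FilterReport]
    standardised: SomaDataset
    corrected: SomaDataset                      # log scale, batch-corrected
    factors: NormalisationFactors
    pca_standardised: PcaModel
    assignment: BimodalAssignment
    combat_models: dict[str, CombatModel]
    ips_model: IpsModel | None
    ips_scores: dict[str, Any]
    pca_final: dict[str, PcaModel]
    manifest: dict[str, Any]


def _checksum(dataset: SomaDataset) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(dataset.values).tobytes())
    h.update("|".join(dataset.sample_ids).encode())
    h.update("|".join(dataset.seq_ids).encode())
    return h.hexdigest()


def run_pipeline(raw: SomaDataset, paired_raw: SomaDataset | None = None,
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full pipeline on a raw dataset.

    ``paired_raw`` (raw-scale paired spun/unspun dataset) is required when
    any branch applies IPS adjustment; its log transform supplies the
    frozen Cohen's-d weights.
    """
    cfg = config or PipelineConfig()
    branches = cfg.branches()
    manifest: dict[str, Any] = {
        "config": {
            "standardisation_steps": list(cfg.standardisation_steps),
            "log_base": cfg.log_base or "e",
            "gmm_seed": cfg.gmm_seed,
            "combat_order": list(cfg.combat_order),
            "ips_branch": cfg.ips_branch,
            "filters": vars(cfg.filters).copy(),
        },
        "stages": [],
    }

    def stage(name: str, ds: SomaDataset, **extra: Any) -> None:
        manifest["stages"].append({"stage": name, "checksum": _checksum(ds),
                                   "n_samples": len(ds.samples),
                                   "n_somamers": len(ds.somamers), **extra})

    try:
        standardised, factors = run_standardisation(raw, cfg.standardisation_steps)
        stage("standardise", standardised)

        logged = log_transform(standardised, base=cfg.log_base)
        stage("log_transform", logged)

        pca_std = fit_pca(logged)
        assignment = fit_pc2_gmm(pca_std.scores["PC2"], seed=cfg.gmm_seed)
        stage("gmm_pc2", logged,
              gmm_means=list(assignment.means), converged=assignment.converged)

        corrected, combat_models = correct_bimodal_and_plate(
            logged, assignment, order=cfg.combat_order)
        stage("combat", corrected)
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise PipelineError(f"pipeline failed before branching: {exc}") from exc

    ips_model = None
    ips_scores: dict[str, Any] = {}
    if "with_ips" in branches:
        if paired_raw is None:
            raise PipelineError("IPS branch requested but no paired spun/unspun "
                                "dataset supplied for weight estimation")
        paired_log = log_transform(paired_raw, base=cfg.log_base) \
            if paired_raw.scale_state in ("raw", "standardised") else paired_raw
        ips_model = compute_ips_weights(paired_log)

    datasets: dict[str, SomaDataset] = {}
    reports: dict[str, FilterReport] = {}
    pca_final: dict[str, PcaModel] = {}
    for branch in branches:
        try:
            if branch == "with_ips":
                scores = compute_ips(corrected, ips_model)
                ips_scores[branch] = scores
                branch_data = adjust_for_ips(corrected, scores)
            else:
                branch_data = corrected
            filtered, report = apply_filters(branch_data, standardised, cfg.filters)
            datasets[branch] = filtered
            reports[branch] = report
            pca_final[branch] = fit_pca(filtered)
            stage(f"filter[{branch}]", filtered,
                  final_counts=list(report.final_counts))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"pipeline failed in branch {branch!r}: {exc}") from exc

    return PipelineResult(
        datasets=datasets, reports=reports, standardised=standardised,
        corrected=corrected, factors=factors, pca_standardised=pca_std,
        assignment=assignment, combat_models=combat_models,
        ips_model=ips_model, ips_scores=ips_scores, pca_final=pca_final,
        manifest=manifest)
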