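"""Synthetic multi-plate SomaScan-style datasets with planted technical structure.

The generator emulates the plate design of a large multi-centre run — per 96-well
plate: 83 participant study wells, one pooled OA and one pooled injury
replicate, five plasma calibrators, three plasma QC wells and three blanks —
and plants, on the log scale, every technical effect the QC pipeline is
designed to detect and remove:

* a dominant intracellular-contamination factor ``u_i * lambda_p`` whose
  per-SOMAmer loadings grow as baseline abundance falls,
* a bimodal high/low processing artefact that flips between laboratory
  processing batches,
* multiplicative plate, well-position and per-(plate, SOMAmer) calibration
  effects,
* blood-staining, sample-age and freeze-thaw confounder effects on
  designated SOMAmer subsets,
* planted bad SOMAmers (technical-variance inflation) and bad samples
  (sub-LOD, PC-space outlier, total-RFU outlier, vendor-flagged).

Every random draw comes from substreams derived from a single mandatory
seed (one fixed offset per effect), so toggling one effect leaves all other
draws unchanged, and identical seeds give bitwise-identical datasets.  The
accompanying :class:`TruthRecord` is the oracle for downstream tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .dataset import ALL_WELLS, SomaDataset, empty_sample_table, empty_somamer_table

# fixed substream offsets: one per planted effect (ablation-stable)
_STREAMS = {
    "somamers": 1, "layout": 2, "intracellular": 3, "bimodal": 4,
    "plate": 5, "well": 6, "calibration": 7, "blood": 8, "age_ft": 9,
    "noise": 10, "bad_entities": 11, "pairs": 12, "bio": 13,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


def _draw_u(rng: np.random.Generator, size, sigma: float) -> np.ndarray:
    """Latent intracellular score: lognormal, winsorised at exp(2*sigma)
    (contamination saturates; keeps the linear-scale tail physical)."""
    return np.minimum(rng.lognormal(0.0, sigma, size), np.exp(2.0 * sigma))


@dataclass
class SynthConfig:
    """Generator configuration.  Defaults mirror a large multi-centre study design
    at desk scale (22 plates, 600 SOMAmers standing in for 7596)."""

    seed: int
    n_plates: int = 22
    somamer_count: int = 600
    n_hyb_controls: int = 4
    n_control_somamers: int = 8      # spuriomer/deprecated/non-biotin/non-human
    dilution_bin_proportions: tuple[float, float, float] = (0.70, 0.25, 0.05)

    # log-scale effect sizes
    baseline_mean: float = 7.6       # log RFU, exp() ~ 2000 RFU
    baseline_sd: float = 0.8
    intracellular_sigma: float = 0.4    # lognormal sigma of the latent score
    intracellular_lambda_max: float = 1.6
    bimodal_fraction: float = 0.30
    bimodal_effect: float = 0.7      # total high-low separation, log units
    batch_size: int = 24
    batch_flip_prob: float = 0.5
    within_batch_flip_prob: float = 0.02
    plate_effect_sd: float = 0.10
    well_gradient_amplitude: float = 0.12
    well_noise_sd: float = 0.24
    calibration_effect_sd: float = 0.05
    calibrator_noise_sd: float = 0.05   # plasma calibrators: technical noise only
    blood_grade_probs: tuple[float, ...] = (0.75, 0.15, 0.07, 0.03)
    hba_effect: float = 0.8          # per blood-grade step on the HBA SOMAmer
    blood_aux_count: int = 5
    blood_aux_effect: float = 0.3
    blood_missing_fraction: float = 0.2
    age_affected_count: int = 35
    age_effect: float = 0.05         # log units per year
    ft_affected_count: int = 15
    ft_effect: float = 0.15          # log units per freeze-thaw
    # biological variation of study samples: a low-rank correlated module
    # structure (protein co-regulation) plus an independent residual; the
    # per-SOMAmer biological variance is bio_factor_var + bio_noise_sd**2
    n_bio_factors: int = 8
    bio_factor_var: float = 0.10
    bio_noise_sd: float = 0.15
    noise_sd: float = 0.2            # technical noise, every well
    blank_level: float = np.log(50.0)
    blank_sd: float = 0.1

    # planted bad entities
    low_r2_count: int = 30
    low_r2_noise_multiplier: float = 4.0
    # handling-sensitive reagents: pooled aliquots are thawed per plate, so
    # their replicate noise exceeds the single-thaw study-sample noise
    low_r2_pooled_noise_multiplier: float = 1.5
    n_lod_fail: int = 10
    lod_fail_fraction: float = 0.35  # fraction of a degraded sample's values at floor
    n_pc_outlier: int = 5
    pc_outlier_delta: float = 1.5
    n_total_rfu_outlier: int = 3
    total_rfu_multiplier: float = 4.0
    n_vendor_flag: int = 2

    # paired spun/unspun generation
    spun_increment: float = 1.5

    @classmethod
    def normalisation_benchmark(cls, seed: int, n_plates: int = 4) -> "SynthConfig":
        """Clean technical-structure fixture: the full plate design and all
        well/plate/calibration/intracellular/bimodal effects, but no planted
        pathological SOMAmers or samples.  Used to measure normalisation
        benefit, where catastrophic planted reagents would drown the
        replicate %CV signal."""
        return cls(seed=seed, n_plates=n_plates,
                   low_r2_count=0, n_lod_fail=0, n_pc_outlier=0,
                   n_total_rfu_outlier=0, n_vendor_flag=0)

    def validate(self) -> None:
        if self.n_plates < 1 or self.somamer_count < 10:
            raise ValueError("config too small to generate a dataset")
        n_study = 83 * self.n_plates
        n_bad = (self.n_lod_fail + self.n_pc_outlier
                 + self.n_total_rfu_outlier + self.n_vendor_flag)
        if n_bad > n_study:
            raise ValueError(f"{n_bad} planted bad samples exceed {n_study} study samples")
        n_protein = self.somamer_count - self.n_hyb_controls - self.n_control_somamers
        pool = int((1.0 - self.bimodal_fraction) * n_protein)   # non-bimodal proteins
        n_bad_p = (self.low_r2_count + self.age_affected_count
                   + self.ft_affected_count + 1 + self.blood_aux_count)
        if n_bad_p > pool:
            raise ValueError(f"{n_bad_p} planted special SOMAmers exceed the "
                             f"{pool} non-bimodal proteins available")
        if self.low_r2_count > pool // 2:
            raise ValueError("low_r2_count exceeds the high-abundance half of "
                             "the non-bimodal protein pool")


@dataclass
class TruthRecord:
    """Ground truth for a generated dataset (test oracle; synthetic)."""

    intracellular_score: pd.Series           # per sample u_i (NaN for controls)
    intracellular_loading: pd.Series         # per SOMAmer lambda_p
    bimodal_status: pd.Series                # +1 high / -1 low / NaN
    bimodal_somamers: list[str]
    bimodal_orientation: pd.Series           # +-1 per affected SOMAmer
    plate_log_factor: pd.Series              # per plate
    well_log_factor: pd.DataFrame            # (plate_id, well) -> log factor
    calibration_log_factor: pd.DataFrame     # plates x seq_ids
    baseline: pd.Series                      # per SOMAmer log baseline
    technical_sd: pd.Series                  # per SOMAmer
    control_somamers: list[str]              # removed by the control filter
    low_r2_somamers: list[str]
    age_somamers: list[str]
    ft_somamers: list[str]
    hba_seq_id: str
    blood_aux_somamers: list[str]
    bad_samples: dict[str, list[str]]        # failure mode -> sample ids
    true_log_biological: pd.DataFrame | None = None  # noiseless biological signal
    extras: dict[str, Any] = field(default_factory=dict)

    def to_json_dict(self) -> dict[str, Any]:
        """JSON-serialisable summary (drops the dense biological matrix)."""
        return {
            "intracellular_score": self.intracellular_score.dropna().to_dict(),
            "bimodal_status": self.bimodal_status.dropna().astype(int).to_dict(),
            "bimodal_somamers": self.bimodal_somamers,
            "plate_log_factor": self.plate_log_factor.to_dict(),
            "control_somamers": self.control_somamers,
            "low_r2_somamers": self.low_r2_somamers,
            "age_somamers": self.age_somamers,
            "ft_somamers": self.ft_somamers,
            "hba_seq_id": self.hba_seq_id,
            "bad_samples": self.bad_samples,
        }


def _make_somamers(cfg: SynthConfig) -> tuple[pd.DataFrame, dict[str, Any]]:
    rng = _rng(cfg.seed, "somamers")
    n = cfg.somamer_count
    n_hyb, n_ctrl = cfg.n_hyb_controls, cfg.n_control_somamers
    n_protein = n - n_hyb - n_ctrl
    seq_ids = [f"SL{i:05d}" for i in range(1, n + 1)]

    types = ["hyb_control_elution"] * n_hyb
    ctrl_cycle = ["spuriomer", "deprecated", "non_biotin", "non_cleavable"]
    types += [ctrl_cycle[i % 4] for i in range(max(0, n_ctrl - 1))]
    types += ["protein"]  # the non-human protein control
    types += ["protein"] * n_protein
    organism = ["human"] * (n_hyb + n_ctrl - 1) + ["mouse"] + ["human"] * n_protein

    baseline = np.empty(n)
    baseline[:n_hyb] = rng.normal(np.log(1000.0), 0.2, n_hyb)
    baseline[n_hyb:n_hyb + n_ctrl] = rng.normal(np.log(200.0), 0.5, n_ctrl)
    baseline[n_hyb + n_ctrl:] = rng.normal(cfg.baseline_mean, cfg.baseline_sd, n_protein)

    # dilution bins follow abundance: the most abundant proteins are measured
    # at the strongest dilution (noisy baseline rank, so the measured RFU
    # ranges of the bins overlap as in the real assay)
    bins = np.array([0.20, 0.005, 0.00005])
    prot = slice(n_hyb + n_ctrl, n)
    p_lo, p_mid, p_hi = cfg.dilution_bin_proportions
    order = np.argsort(-(baseline[prot] + rng.normal(0.0, 0.4, n_protein)))
    bin_assign = np.zeros(n_protein, dtype=int)
    n_hi = int(round(p_hi * n_protein))
    n_mid = int(round(p_mid * n_protein))
    bin_assign[order[:n_hi]] = 2
    bin_assign[order[n_hi:n_hi + n_mid]] = 1
    dilution = np.full(n, 0.005)
    dilution[prot] = bins[bin_assign]

    # intracellular loadings grow linearly with the rank of *low* true
    # (dilution-adjusted) abundance: the factor loads on scarce proteins
    # while total RFU, dominated by abundant proteins with ~zero loadings,
    # stays nearly untouched
    lam = np.zeros(n)
    true_log_abundance = baseline[prot] - np.log(dilution[prot])
    q = pd.Series(-true_log_abundance).rank(pct=True).to_numpy()  # 1 = scarcest
    lam[prot] = cfg.intracellular_lambda_max * q * rng.uniform(0.5, 1.0, n_protein)

    # secretion classes, enriched for nuclear/non-secreted at high loading
    sec = np.empty(n, dtype=object)
    sec[:n_hyb + n_ctrl] = "unknown"
    lam_hi = lam[prot] > np.quantile(lam[prot], 0.75)
    p_hi = np.array([0.20, 0.45, 0.20, 0.15])
    p_lo = np.array([0.55, 0.08, 0.20, 0.17])
    classes = np.array(["secreted", "nuclear_not_secreted", "not_secreted_other", "unknown"])
    draws = np.where(lam_hi[:, None],
                     rng.random((n_protein, 1)) < np.cumsum(p_hi)[None, :],
                     rng.random((n_protein, 1)) < np.cumsum(p_lo)[None, :])
    sec[prot] = classes[np.argmax(draws, axis=1)]

    cal_ref_log = baseline + rng.normal(0.0, 0.3, n)
    cal_ref = np.where(np.array(types) == "protein", np.exp(cal_ref_log), np.nan)

    table = empty_somamer_table(n)
    table["seq_id"] = pd.array(seq_ids, dtype="string")
    table["target_name"] = pd.array([f"Target_{s}" for s in seq_ids], dtype="string")
    table["dilution_bin"] = dilution
    table["organism"] = pd.array(organism, dtype="string")
    table["somamer_type"] = pd.array(types, dtype="string")
    table["secretion_class"] = pd.array(list(sec), dtype="string")
    table["calibrator_reference"] = cal_ref
    table["is_hyb_control"] = np.array(types) == "hyb_control_elution"

    aux = {"baseline": baseline, "lambda": lam, "cal_base_log": cal_ref_log,
           "n_protein": n_protein, "protein_slice": prot}
    return table, aux


def _plate_layout(cfg: SynthConfig) -> pd.DataFrame:
    """Sample table for the full multi-plate run (roles randomised to wells)."""
    rng = _rng(cfg.seed, "layout")
    rows = []
    study_counter = 0
    for q in range(cfg.n_plates):
        plate = f"P{q + 1:02d}"
        wells = list(ALL_WELLS)
        rng.shuffle(wells)
        roles = (["study"] * 83 + ["pooled_oa", "pooled_injury"]
                 + ["calibrator"] * 5 + ["plasma_qc"] * 3 + ["blank"] * 3)
        for well, role in zip(wells, roles):
            if role == "study":
                study_counter += 1
                sid = f"S{study_counter:04d}"
                pid = f"PT{study_counter:04d}"
                dg = "oa" if rng.random() < 0.6 else "injury"
            elif role in ("pooled_oa", "pooled_injury"):
                sid = f"{role.upper()}-{plate}"
                pid = role.upper()
                dg = "oa" if role == "pooled_oa" else "injury"
            else:
                sid = f"{role.upper()}-{plate}-{well}"
                pid = sid
                dg = "none"
            rows.append({"sample_id": sid, "participant_id": pid, "role": role,
                         "plate_id": plate, "well": well, "disease_group": dg})
    table = empty_sample_table(len(rows))
    for col in ("sample_id", "participant_id", "role", "plate_id", "well", "disease_group"):
        table[col] = pd.array([r[col] for r in rows], dtype="string")
    table["cohort"] = pd.array(["synthetic"] * len(rows), dtype="string")
    return table


def generate_dataset(config: SynthConfig) -> tuple[SomaDataset, TruthRecord]:
    """Generate a full multi-plate raw-scale dataset plus its ground truth."""
    cfg = config
    cfg.validate()
    somamers, aux = _make_somamers(cfg)
    samples = _plate_layout(cfg)
    n_samples, n_som = len(samples), len(somamers)
    seq_ids = somamers["seq_id"].astype(str).tolist()
    sample_ids = samples["sample_id"].astype(str).tolist()
    baseline, lam = aux["baseline"], aux["lambda"]
    types = somamers["somamer_type"].astype(str).to_numpy()
    is_hyb = types == "hyb_control_elution"
    is_protein = (types == "protein") & (somamers["organism"].astype(str).to_numpy() == "human")
    role = samples["role"].astype(str).to_numpy()
    plate = samples["plate_id"].astype(str).to_numpy()
    plates = sorted(set(plate))
    wells = samples["well"].astype(str).to_numpy()

    # --- technical factors ----------------------------------------------------
    # stratified draw: evenly spaced normal quantiles, randomly permuted, so
    # the planted between-plate variance is at its nominal size in every run
    rngp = _rng(cfg.seed, "plate")
    from scipy.stats import norm as _norm
    qs = _norm.ppf((np.arange(len(plates)) + 0.5) / len(plates))
    plate_fac = pd.Series(cfg.plate_effect_sd * rngp.permutation(qs), index=plates)
    rngw = _rng(cfg.seed, "well")
    well_rows = []
    for q in plates:
        for w in ALL_WELLS:
            col = int(w[1:])
            grad = cfg.well_gradient_amplitude * (col - 6.5) / 11.0
            well_rows.append({"plate_id": q, "well": w,
                              "log_factor": grad + rngw.normal(0.0, cfg.well_noise_sd)})
    well_fac = pd.DataFrame(well_rows).set_index(["plate_id", "well"])["log_factor"]
    rngc = _rng(cfg.seed, "calibration")
    cal_fac = pd.DataFrame(
        rngc.normal(0.0, cfg.calibration_effect_sd, (len(plates), n_som)),
        index=plates, columns=seq_ids)

    sample_plate_fac = plate_fac.loc[plate].to_numpy()
    sample_well_fac = well_fac.loc[list(zip(plate, wells))].to_numpy()
    sample_cal_fac = cal_fac.loc[plate].to_numpy()          # samples x somamers
    tech_term = (sample_plate_fac + sample_well_fac)[:, None] + sample_cal_fac

    # --- latent biology -------------------------------------------------------
    rngu = _rng(cfg.seed, "intracellular")
    u = np.full(n_samples, np.nan)
    is_study = role == "study"
    is_pooled = np.isin(role, ["pooled_oa", "pooled_injury"])
    u[is_study] = _draw_u(rngu, is_study.sum(), cfg.intracellular_sigma)
    u_pool = {"pooled_oa": float(_draw_u(rngu, None, cfg.intracellular_sigma)),
              "pooled_injury": float(_draw_u(rngu, None, cfg.intracellular_sigma))}
    for r, v in u_pool.items():
        u[role == r] = v

    rngb = _rng(cfg.seed, "bio")
    bio = np.zeros((n_samples, n_som))
    n_study = int(is_study.sum())
    w_f = None
    if cfg.n_bio_factors > 0 and cfg.bio_factor_var > 0:
        v_k = 0.9 ** np.arange(cfg.n_bio_factors)
        v_k = cfg.bio_factor_var * v_k / v_k.sum()      # per-SOMAmer variance split
        z_f = rngb.normal(0.0, 1.0, (n_study, cfg.n_bio_factors))
        w_f = rngb.normal(0.0, 1.0, (cfg.n_bio_factors, n_som)) * np.sqrt(v_k)[:, None]
        bio[is_study] = z_f @ w_f
    bio[is_study] += rngb.normal(0.0, cfg.bio_noise_sd, (n_study, n_som))
    # each pool is a 6-donor mixture: its biological offset is the donors'
    # mean factor coordinate, i.e. a point inside the factor subspace (an
    # orthogonal pool-specific direction would show up as its own PC axis)
    pool_offset = {}
    for r in ("pooled_oa", "pooled_injury"):
        if w_f is not None:
            z_pool = rngu.normal(0.0, 1.0 / np.sqrt(6.0), cfg.n_bio_factors)
            pool_offset[r] = z_pool @ w_f
        else:
            pool_offset[r] = np.zeros(n_som)

    # --- processing order, batches and the bimodal artefact -------------------
    # study samples are processed in randomised order in consecutive batches;
    # each pooled sample is a sub-aliquot of a single processed batch, so all
    # of its plate replicates share one fixed status
    rngbi = _rng(cfg.seed, "bimodal")
    proc_idx = np.nonzero(is_study)[0]
    order = rngbi.permutation(len(proc_idx))
    proc_order = np.full(n_samples, pd.NA, dtype=object)
    proc_batch = np.full(n_samples, pd.NA, dtype=object)
    status = np.full(n_samples, np.nan)
    batch_of = order // cfg.batch_size
    n_batches = int(batch_of.max()) + 1
    batch_status = np.empty(n_batches)
    batch_status[0] = 1.0 if rngbi.random() < 0.5 else -1.0
    for bidx in range(1, n_batches):
        flip = rngbi.random() < cfg.batch_flip_prob
        batch_status[bidx] = -batch_status[bidx - 1] if flip else batch_status[bidx - 1]
    for k, i in enumerate(proc_idx):
        proc_order[i] = int(order[k]) + 1
        proc_batch[i] = int(batch_of[k])
        s = batch_status[batch_of[k]]
        if rngbi.random() < cfg.within_batch_flip_prob:
            s = -s
        status[i] = s
    status[role == "pooled_oa"] = batch_status[0]
    status[role == "pooled_injury"] = batch_status[0]
    proc_batch[is_pooled] = 0

    prot_ids = np.array(seq_ids)[is_protein]
    n_bimodal = int(round(cfg.bimodal_fraction * is_protein.sum()))
    bim_ids = rngbi.choice(prot_ids, size=n_bimodal, replace=False).tolist()
    orientation = pd.Series(rngbi.choice([-1.0, 1.0], size=n_bimodal), index=bim_ids)
    bim_col = np.isin(seq_ids, bim_ids)
    bim_dir = np.zeros(n_som)
    bim_dir[bim_col] = orientation.loc[np.array(seq_ids)[bim_col]].to_numpy()
    status_term = np.nan_to_num(status)[:, None] * bim_dir[None, :] * (cfg.bimodal_effect / 2.0)

    # --- confounders (study samples only) -------------------------------------
    rngbl = _rng(cfg.seed, "blood")
    grades = np.full(n_samples, pd.NA, dtype=object)
    g_draw = rngbl.choice(np.arange(1, 5), size=is_study.sum(),
                          p=np.asarray(cfg.blood_grade_probs))
    missing = rngbl.random(is_study.sum()) < cfg.blood_missing_fraction
    grade_vals = np.where(missing, -1, g_draw)
    grades[is_study] = [pd.NA if g < 0 else int(g) for g in grade_vals]
    g_full = np.zeros(n_samples)
    g_full[is_study] = g_draw  # true grade drives the effect even when unrecorded

    rnga = _rng(cfg.seed, "age_ft")
    age = np.full(n_samples, np.nan)
    age[is_study] = rnga.uniform(0.0, 10.0, is_study.sum())
    ft = np.full(n_samples, np.nan)
    ft[is_study] = rnga.poisson(1.0, is_study.sum())
    volume = np.full(n_samples, np.nan)
    volume[is_study] = rnga.lognormal(0.0, 0.5, is_study.sum())

    # designated confounder-affected SOMAmer subsets (disjoint, protein only).
    # the variance-inflated ("low R²") reagents are drawn from the
    # high-abundance half, where the intracellular loading is small: their
    # variance is then genuinely technical, not biological
    special_pool = [s for s in prot_ids if s not in set(bim_ids)]
    rngbad = _rng(cfg.seed, "bad_entities")
    prot_baseline = pd.Series(baseline[is_protein], index=prot_ids)
    high_ab = set(prot_baseline[prot_baseline >= prot_baseline.median()].index)
    low_r2_pool = [s for s in special_pool if s in high_ab]
    low_r2_ids = (rngbad.choice(low_r2_pool, size=cfg.low_r2_count,
                                replace=False).tolist()
                  if cfg.low_r2_count else [])
    rest_pool = [s for s in special_pool if s not in set(low_r2_ids)]
    picks = rngbad.choice(rest_pool,
                          size=(cfg.age_affected_count
                                + cfg.ft_affected_count + 1 + cfg.blood_aux_count),
                          replace=False)
    ptr = 0
    age_ids = picks[ptr:ptr + cfg.age_affected_count].tolist(); ptr += cfg.age_affected_count
    ft_ids = picks[ptr:ptr + cfg.ft_affected_count].tolist(); ptr += cfg.ft_affected_count
    hba_id = str(picks[ptr]); ptr += 1
    blood_aux = picks[ptr:ptr + cfg.blood_aux_count].tolist()

    # "dead" reagents: no biological response at all (loading and per-sample
    # biological variation zeroed), inflated technical noise -> V_pooled
    # approaches V_total and the non-technical R² collapses
    lr_col = np.isin(seq_ids, low_r2_ids)
    lam = lam.copy()
    lam[lr_col] = 0.0
    bio[:, lr_col] = 0.0

    conf_term = np.zeros((n_samples, n_som))
    age_col = np.isin(seq_ids, age_ids)
    ft_col = np.isin(seq_ids, ft_ids)
    hba_col = np.array(seq_ids) == hba_id
    aux_col = np.isin(seq_ids, blood_aux)
    conf_term[:, age_col] += np.nan_to_num(age)[:, None] * cfg.age_effect
    conf_term[:, ft_col] += np.nan_to_num(ft)[:, None] * cfg.ft_effect
    conf_term[:, hba_col] += ((g_full - 1).clip(min=0))[:, None] * cfg.hba_effect
    conf_term[:, aux_col] += ((g_full - 1).clip(min=0))[:, None] * cfg.blood_aux_effect

    # --- assemble log-scale matrix --------------------------------------------
    tech_sd = np.full(n_som, cfg.noise_sd)
    tech_sd[np.isin(seq_ids, low_r2_ids)] *= cfg.low_r2_noise_multiplier
    rngn = _rng(cfg.seed, "noise")
    noise = rngn.normal(0.0, 1.0, (n_samples, n_som)) * tech_sd[None, :]
    if lr_col.any():
        noise[np.ix_(is_pooled, lr_col)] *= cfg.low_r2_pooled_noise_multiplier

    log_m = np.empty((n_samples, n_som))
    biological = np.zeros((n_samples, n_som))

    u_term = np.nan_to_num(u)[:, None] * lam[None, :]
    base_signal = baseline[None, :] + u_term + bio + status_term + conf_term
    for r, off in pool_offset.items():
        base_signal[role == r] += off[None, :]
    biological = base_signal.copy()

    log_m[:] = base_signal + tech_term + noise
    # hyb-control columns: spiked into every well, no biology
    hyb_noise = rngn.normal(0.0, 0.1 * cfg.noise_sd, (n_samples, is_hyb.sum()))
    log_m[:, is_hyb] = (baseline[None, is_hyb]
                        + (sample_plate_fac + sample_well_fac)[:, None] + hyb_noise)
    # calibrator and plasma-QC wells: plasma profile at the reference values
    cal_base = aux["cal_base_log"]
    for r, shift_sd in (("calibrator", 0.0), ("plasma_qc", 0.2)):
        m = role == r
        if r == "plasma_qc":
            qc_off = rngn.normal(0.0, shift_sd, n_som)
        else:
            qc_off = np.zeros(n_som)
        vals = (cal_base[None, :] + qc_off[None, :] + tech_term[m]
                + rngn.normal(0.0, cfg.calibrator_noise_sd, (m.sum(), n_som)))
        vals[:, is_hyb] = log_m[m][:, is_hyb]
        log_m[m] = vals
    # blanks: buffer-only noise floor (hyb controls still spiked in)
    m = role == "blank"
    blank_vals = (cfg.blank_level + tech_term[m]
                  + rngn.normal(0.0, cfg.blank_sd, (m.sum(), n_som)))
    blank_vals[:, is_hyb] = log_m[m][:, is_hyb]
    log_m[m] = blank_vals

    # --- planted bad samples (study only, disjoint) ---------------------------
    study_ids = np.array(sample_ids)[is_study]
    n_bad = cfg.n_lod_fail + cfg.n_pc_outlier + cfg.n_total_rfu_outlier + cfg.n_vendor_flag
    bad_pick = rngbad.choice(study_ids, size=n_bad, replace=False)
    ptr = 0
    lod_ids = bad_pick[ptr:ptr + cfg.n_lod_fail].tolist(); ptr += cfg.n_lod_fail
    pc_ids = bad_pick[ptr:ptr + cfg.n_pc_outlier].tolist(); ptr += cfg.n_pc_outlier
    tot_ids = bad_pick[ptr:ptr + cfg.n_total_rfu_outlier].tolist(); ptr += cfg.n_total_rfu_outlier
    flag_ids = bad_pick[ptr:].tolist()

    id_to_row = {s: i for i, s in enumerate(sample_ids)}
    prot_cols = np.nonzero(is_protein)[0]
    # degraded samples: a random subset of values collapses to the noise
    # floor, pushing the sample's sub-LOD fraction past the threshold
    for sid in lod_ids:
        i = id_to_row[sid]
        k = int(round(cfg.lod_fail_fraction * len(prot_cols)))
        cols = rngbad.choice(prot_cols, size=k, replace=False)
        log_m[i, cols] = (cfg.blank_level - 0.5 + tech_term[i, cols]
                          + rngbad.normal(0.0, cfg.blank_sd, k))
    # sign-asymmetric, linear-scale mean-preserving spike: a PC outlier that is
    # not also a total-RFU outlier
    d = cfg.pc_outlier_delta
    p_up = (1.0 - np.exp(-d)) / (np.exp(d) - np.exp(-d))
    for sid in pc_ids:
        i = id_to_row[sid]
        signs = np.where(rngbad.random(len(prot_cols)) < p_up, 1.0, -1.0)
        log_m[i, prot_cols] += d * signs
    for sid in tot_ids:
        i = id_to_row[sid]
        log_m[i, prot_cols] += np.log(cfg.total_rfu_multiplier)

    vendor_flag = np.zeros(n_samples, dtype=bool)
    for sid in flag_ids:
        vendor_flag[id_to_row[sid]] = True

    # --- finalise tables -------------------------------------------------------
    samples["processing_batch"] = pd.array(proc_batch, dtype="Int64")
    samples["processing_order"] = pd.array(proc_order, dtype="Int64")
    samples["spun"] = pd.array(np.where(is_study | is_pooled, True, pd.NA), dtype="boolean")
    samples["blood_grade"] = pd.array(grades, dtype="Int64")
    samples["volume_ml"] = volume
    samples["sample_age_years"] = age
    samples["freeze_thaw_count"] = pd.array(
        [pd.NA if np.isnan(v) else int(v) for v in ft], dtype="Int64")
    samples["vendor_flag"] = pd.array(vendor_flag, dtype="boolean")

    rfu = pd.DataFrame(np.exp(log_m), columns=seq_ids)
    dataset = SomaDataset(rfu=rfu, somamers=somamers, samples=samples, scale_state="raw")
    dataset.log_op("generate_dataset", seed=cfg.seed, n_plates=cfg.n_plates,
                   somamer_count=cfg.somamer_count)

    control_ids = [s for s, t, o in zip(seq_ids, types, somamers["organism"].astype(str))
                   if t != "protein" or o.lower() != "human"]
    truth = TruthRecord(
        intracellular_score=pd.Series(u, index=sample_ids),
        intracellular_loading=pd.Series(lam, index=seq_ids),
        bimodal_status=pd.Series(status, index=sample_ids),
        bimodal_somamers=bim_ids,
        bimodal_orientation=orientation,
        plate_log_factor=plate_fac,
        well_log_factor=well_fac.to_frame(),
        calibration_log_factor=cal_fac,
        baseline=pd.Series(baseline, index=seq_ids),
        technical_sd=pd.Series(tech_sd, index=seq_ids),
        control_somamers=control_ids,
        low_r2_somamers=low_r2_ids,
        age_somamers=age_ids,
        ft_somamers=ft_ids,
        hba_seq_id=hba_id,
        blood_aux_somamers=blood_aux,
        bad_samples={"lod": lod_ids, "pca": pc_ids,
                     "total_rfu": tot_ids, "vendor_flag": flag_ids},
        true_log_biological=pd.DataFrame(biological, index=sample_ids, columns=seq_ids),
        extras={"u_pool": u_pool, "blood_grade_true": pd.Series(g_full, index=sample_ids)},
    )
    return dataset, truth


def generate_paired_spun_unspun(config: SynthConfig, n_pairs: int = 18
                                ) -> tuple[SomaDataset, TruthRecord]:
    """Paired spun/unspun aliquots from the same joint aspirate.

    Pair members share every latent term except the intracellular score,
    which is inflated in the unspun member by ``config.spun_increment``.
    Pairing is recorded through a shared ``participant_id``.
    """
    cfg = config
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2 (paired Cohen's d needs >= 2 pairs)")
    somamers, aux = _make_somamers(cfg)
    n_som = len(somamers)
    seq_ids = somamers["seq_id"].astype(str).tolist()
    baseline, lam = aux["baseline"], aux["lambda"]

    rng = _rng(cfg.seed, "pairs")
    u_spun = _draw_u(rng, n_pairs, cfg.intracellular_sigma)
    u_unspun = u_spun + cfg.spun_increment
    bio_sd = float(np.sqrt(cfg.bio_factor_var + cfg.bio_noise_sd ** 2))
    bio = rng.normal(0.0, bio_sd, (n_pairs, n_som))

    rows, mats = [], []
    for j in range(n_pairs):
        for spun, uval in ((True, u_spun[j]), (False, u_unspun[j])):
            noise = rng.normal(0.0, cfg.noise_sd, n_som)
            mats.append(baseline + uval * lam + bio[j] + noise)
            rows.append({"sample_id": f"PAIR{j + 1:02d}-{'S' if spun else 'U'}",
                         "participant_id": f"PAIR{j + 1:02d}", "spun": spun})
    n_samples = len(rows)
    samples = empty_sample_table(n_samples)
    samples["sample_id"] = pd.array([r["sample_id"] for r in rows], dtype="string")
    samples["participant_id"] = pd.array([r["participant_id"] for r in rows], dtype="string")
    samples["role"] = pd.array(["study"] * n_samples, dtype="string")
    samples["plate_id"] = pd.array(["P01"] * n_samples, dtype="string")
    samples["well"] = pd.array([ALL_WELLS[i % 96] for i in range(n_samples)], dtype="string")
    samples["disease_group"] = pd.array(["oa"] * n_samples, dtype="string")
    samples["spun"] = pd.array([r["spun"] for r in rows], dtype="boolean")
    samples["vendor_flag"] = pd.array([False] * n_samples, dtype="boolean")

    rfu = pd.DataFrame(np.exp(np.vstack(mats)), columns=seq_ids)
    dataset = SomaDataset(rfu=rfu, somamers=somamers, samples=samples, scale_state="raw")
    dataset.log_op("generate_paired_spun_unspun", seed=cfg.seed, n_pairs=n_pairs,
                   increment=cfg.spun_increment)

    sample_ids = samples["sample_id"].astype(str).tolist()
    u_all = np.empty(n_samples)
    u_all[0::2], u_all[1::2] = u_spun, u_unspun
    truth = TruthRecord(
        intracellular_score=pd.Series(u_all, index=sample_ids),
        intracellular_loading=pd.Series(lam, index=seq_ids),
        bimodal_status=pd.Series(np.nan, index=sample_ids),
        bimodal_somamers=[], bimodal_orientation=pd.Series(dtype=float),
        plate_log_factor=pd.Series(dtype=float),
        well_log_factor=pd.DataFrame(), calibration_log_factor=pd.DataFrame(),
        baseline=pd.Series(baseline, index=seq_ids),
        technical_sd=pd.Series(cfg.noise_sd, index=seq_ids),
        control_somamers=[], low_r2_somamers=[], age_somamers=[], ft_somamers=[],
        hba_seq_id="", blood_aux_somamers=[],
        bad_samples={}, true_log_biological=None,
        extras={"u_spun": u_spun, "u_unspun": u_unspun},
    )
    return dataset, truth
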