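"""Synthetic study generator emulating a paired-limb methylation-array design.

The generator emits everything the analysis chain consumes — probe
manifest, beta matrix, RNA-seq counts, sample sheet, a generative clock
and a ground-truth record — with the statistical structure the pipeline
assumes:

* three arms (young-vehicle, old-vehicle, old-senolytic), each animal
  contributing a PBS control limb and a BaCl2-injured limb;
* per-probe baselines drawn from feature-class-specific Beta
  distributions; sample values built on the logit scale (injury effect on
  responsive promoter CpGs, senolytic extra shift, chip/batch effect, one
  latent unwanted-variation factor with per-probe loadings, per-animal
  shared intercept, residual noise) and mapped back through the inverse
  logit so betas stay in [0, 1] without clipping artifacts;
* clock CpGs carrying a linear-in-beta age trend whose exact linear
  inverse is emitted as the generative ClockModel; in BaCl2 limbs of old
  animals the effective age is pulled toward the young mean by the
  rejuvenation factor rho;
* negative-binomial RNA-seq counts whose log2 mean is shifted by
  coupling_gamma times the promoter methylation loss for coupled genes,
  so hypomethylation drives up-regulation.

Identical config + seed reproduces byte-identical artifacts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ARMS, BetaMatrix, GeneModel, ValidationError

log = logging.getLogger("methregen.simulate")

__all__ = ["ClockSimConfig", "SimulationConfig", "GroundTruth", "SimulatedStudy",
           "simulate_study", "emit_de_table"]


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class ClockSimConfig:
    n_clock_cpgs: int = 30
    slope_per_week: float = 0.002  # beta units per week of age
    young_age_weeks: float = 24.0
    old_age_weeks: float = 104.0
    regen_rejuvenation_rho: float = 0.5  # 0 = no rejuvenation, 1 = fully young
    age_jitter_sd_weeks: float = 2.0  # per-animal biological-age spread
    noise_sd_beta: float = 0.02  # beta-scale noise on clock CpGs

    def __post_init__(self):
        if not (0.0 <= self.regen_rejuvenation_rho <= 1.0):
            raise ValidationError("regen_rejuvenation_rho must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults are the desk-scale study: 2,000 genes, ~16,000 annotated
    probes plus controls and clock CpGs, 26 animals (52 samples) split
    YV=6, OV=11, OS=9 as in the emulated design.
    """

    seed: int = 0
    n_genes: int = 2000
    probes_per_gene: dict = field(
        default_factory=lambda: {
            "promoter": 2, "exon": 2, "intron": 2,
            "five_prime_utr": 1, "three_prime_utr": 1,
        }
    )
    n_animals: dict = field(default_factory=lambda: {"YV": 6, "OV": 11, "OS": 9})
    effect_fraction: float = 0.10  # fraction of promoter CpGs injury-responsive
    delta_beta: float = -0.20  # mean beta shift of responsive CpGs in BaCl2 limbs
    senolytic_extra_delta: float = -0.05  # additional shift in the OS arm
    batch_sd: float = 0.10  # logit-scale chip effect SD
    ruv_sd: float = 0.30  # logit-scale SD of the single latent factor
    noise_sd: float = 0.15  # logit-scale residual SD
    animal_sd: float = 0.05  # logit-scale shared per-animal intercept SD
    coupling_gamma: float = 4.0  # log2 expression per unit promoter-beta loss
    coupled_fraction: float = 0.5  # fraction of responsive genes coupled to expression
    nb_dispersion: float = 0.05  # NB variance = mu + alpha mu^2
    lib_size_range: tuple = (0.7, 1.3)
    n_control_probes: int = 200
    samples_per_chip: int = 8
    promoter_window: tuple = (-1000, 500)
    gene_span_bp: int = 10_000
    gene_spacing_bp: int = 1_000_000
    clock: ClockSimConfig = field(default_factory=ClockSimConfig)

    def __post_init__(self):
        if isinstance(self.clock, dict):
            object.__setattr__(self, "clock", ClockSimConfig(**self.clock))
        for name in ("effect_fraction", "coupled_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1]")
        for name in ("batch_sd", "ruv_sd", "noise_sd", "animal_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.nb_dispersion < 0:
            raise ValidationError("nb_dispersion must be >= 0")


@dataclass
class GroundTruth:
    """Planted signals for downstream verification."""

    responsive_probes: pd.DataFrame  # probe_id, gene_id, delta_beta_target, logit shifts
    coupled_genes: pd.DataFrame  # gene_id, coupling_sign
    control_probes: list
    clock_probes: pd.DataFrame  # probe_id, baseline, slope
    true_clock: "object"  # ClockModel
    true_ages: pd.Series  # effective age per sample (weeks)
    batch_effects: pd.Series  # per batch
    ruv_factor: pd.Series  # per sample
    animal_intercepts: pd.Series  # per animal


@dataclass
class SimulatedStudy:
    manifest: pd.DataFrame
    beta: BetaMatrix
    counts: pd.DataFrame  # genes x samples
    sheet: pd.DataFrame
    genes: list
    clock: "object"
    truth: GroundTruth


_BASELINE_BETA_PARAMS = {
    # (a, b) of the Beta distribution per feature class; promoters and 5'UTRs
    # sit lower than gene bodies but off the floor, so a -0.2 injury shift
    # stays inside the unit interval
    "promoter": (2.5, 5.0),
    "five_prime_utr": (2.0, 5.0),
    "exon": (5.0, 3.0),
    "intron": (4.0, 3.0),
    "three_prime_utr": (4.0, 3.0),
    "intergenic": (3.0, 3.0),
}


def _build_sheet(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for arm in ("YV", "OV", "OS"):
        age_group, treatment = ARMS[arm]
        for i in range(cfg.n_animals.get(arm, 0)):
            animal = f"{arm}{i + 1:02d}"
            for limb in ("PBS", "BaCl2"):
                rows.append(
                    {
                        "sample_id": f"{animal}_{limb}",
                        "animal_id": animal,
                        "age_group": age_group,
                        "treatment": treatment,
                        "limb": limb,
                    }
                )
    sheet = pd.DataFrame(rows)
    # sentrix-style chip assignment: consecutive samples in shuffled order
    order = rng.permutation(len(sheet))
    chip = np.empty(len(sheet), dtype=object)
    for pos, idx in enumerate(order):
        chip[idx] = f"chip{pos // cfg.samples_per_chip + 1:02d}"
    sheet["batch"] = chip
    return sheet


def _build_manifest(cfg: SimulationConfig, rng: np.random.Generator):
    genes: list[GeneModel] = []
    records = []
    chroms = [f"chr{c}" for c in range(1, 20)]
    per_chrom = math.ceil(cfg.n_genes / len(chroms))
    k = 0
    for g in range(cfg.n_genes):
        chrom = chroms[g // per_chrom]
        slot = g % per_chrom
        start = 100_000 + slot * cfg.gene_spacing_bp  # 0-based
        end = start + cfg.gene_span_bp
        strand = "+" if g % 2 == 0 else "-"
        tss = start + 1 if strand == "+" else end
        gid = f"gene{g + 1:05d}"
        genes.append(GeneModel(gid, gid.upper(), chrom, strand, tss, start, end))
        sgn = 1 if strand == "+" else -1
        for fc, n_probes in cfg.probes_per_gene.items():
            for j in range(n_probes):
                if fc == "promoter":
                    lo, hi = cfg.promoter_window
                    d = int(rng.integers(lo, hi + 1))
                else:
                    offsets = {
                        "five_prime_utr": (50, 500),
                        "exon": (500, cfg.gene_span_bp - 2000),
                        "intron": (1000, cfg.gene_span_bp - 1000),
                        "three_prime_utr": (cfg.gene_span_bp - 500, cfg.gene_span_bp),
                    }
                    a, b = offsets[fc]
                    d = int(rng.integers(a, b))
                pos1 = tss + sgn * d  # 1-based, signed distance along the strand
                pos1 = max(1, pos1)
                k += 1
                records.append(
                    {
                        "probe_id": f"cg{k:07d}",
                        "chrom": chrom,
                        "pos": pos1,
                        "gene_id": gid,
                        "feature_class": fc,
                        "tss_distance": d,
                    }
                )
    # negative-control probes: intergenic, never responsive
    far = 50_000_000
    for j in range(cfg.n_control_probes):
        k += 1
        records.append(
            {
                "probe_id": f"ctl{j + 1:05d}",
                "chrom": chroms[j % len(chroms)],
                "pos": far + j * 1_000,
                "gene_id": None,
                "feature_class": "intergenic",
                "tss_distance": 0,
            }
        )
    manifest = pd.DataFrame.from_records(records)
    return genes, manifest


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate one complete synthetic study (deterministic in config.seed)."""
    from .clocks import ClockModel

    cfg = config
    rng = np.random.default_rng(cfg.seed)
    sheet = _build_sheet(cfg, rng)
    genes, manifest = _build_manifest(cfg, rng)
    n_samples = len(sheet)
    sample_ids = sheet["sample_id"].tolist()

    # --- planted signals -------------------------------------------------
    prom = manifest[manifest["feature_class"] == "promoter"]
    gene_ids = np.array([g.gene_id for g in genes])
    n_resp_genes = int(round(cfg.effect_fraction * len(gene_ids)))
    n_prom_per_gene = cfg.probes_per_gene.get("promoter", 0)
    if n_resp_genes > 0 and n_prom_per_gene == 0:
        raise ValidationError("effect_fraction > 0 but no promoter probes configured")
    if n_resp_genes * n_prom_per_gene > len(prom):
        raise ValidationError("more responsive probes requested than promoter probes exist")
    resp_genes = rng.choice(gene_ids, size=n_resp_genes, replace=False) if n_resp_genes else np.array([], dtype=object)
    resp_gene_set = set(resp_genes)
    responsive_mask = manifest["gene_id"].isin(resp_gene_set) & (
        manifest["feature_class"] == "promoter"
    )
    n_coupled = int(round(cfg.coupled_fraction * n_resp_genes))
    coupled = rng.choice(resp_genes, size=n_coupled, replace=False) if n_coupled else np.array([], dtype=object)
    coupled_set = set(coupled)

    # --- baselines and logit-scale assembly ------------------------------
    n_probes = len(manifest)
    base = np.empty(n_probes)
    for fc, (a, b) in _BASELINE_BETA_PARAMS.items():
        m = (manifest["feature_class"] == fc).to_numpy()
        base[m] = rng.beta(a, b, size=m.sum())
    base = np.clip(base, 0.02, 0.98)
    logit_base = _logit(base)

    resp_idx = np.flatnonzero(responsive_mask.to_numpy())
    target = np.clip(base[resp_idx] + cfg.delta_beta, 0.02, 0.98)
    shift_v = _logit(target) - logit_base[resp_idx]  # vehicle arms
    target_s = np.clip(base[resp_idx] + cfg.delta_beta + cfg.senolytic_extra_delta, 0.02, 0.98)
    shift_s = _logit(target_s) - logit_base[resp_idx]  # senolytic arm

    batches = sorted(sheet["batch"].unique())
    batch_eff = pd.Series(rng.normal(0.0, cfg.batch_sd, len(batches)), index=batches)
    animals = sheet["animal_id"].unique()
    animal_eff = pd.Series(rng.normal(0.0, cfg.animal_sd, len(animals)), index=animals)
    ruv_factor = pd.Series(rng.normal(0.0, 1.0, n_samples), index=sample_ids)
    loadings = rng.normal(0.0, cfg.ruv_sd, n_probes)

    is_bacl2 = (sheet["limb"] == "BaCl2").to_numpy()
    is_os = (sheet["treatment"] == "senolytic").to_numpy()

    L = np.tile(logit_base[:, None], (1, n_samples))
    eff = np.zeros((len(resp_idx), n_samples))
    eff[:, is_bacl2 & ~is_os] = shift_v[:, None]
    eff[:, is_bacl2 & is_os] = shift_s[:, None]
    L[resp_idx] += eff
    L += batch_eff[sheet["batch"]].to_numpy()[None, :]
    L += animal_eff[sheet["animal_id"]].to_numpy()[None, :]
    L += loadings[:, None] * ruv_factor.to_numpy()[None, :]
    if cfg.noise_sd > 0:
        L += rng.normal(0.0, cfg.noise_sd, L.shape)
    beta_vals = _expit(L)

    # --- clock CpGs (beta-scale age trend, exact linear inverse) ----------
    ck = cfg.clock
    n_ck = ck.n_clock_cpgs
    span = ck.slope_per_week * ck.old_age_weeks
    sign = np.where(rng.random(n_ck) < 0.5, 1.0, -1.0)
    slope = sign * ck.slope_per_week
    a0 = np.where(
        sign > 0,
        rng.uniform(0.05, 0.93 - span, n_ck),
        rng.uniform(0.07 + span, 0.95, n_ck),
    )
    chrono = np.where(sheet["age_group"] == "old", ck.old_age_weeks, ck.young_age_weeks)
    jitter = pd.Series(
        rng.normal(0.0, ck.age_jitter_sd_weeks, len(animals)), index=animals
    )
    chrono = chrono + jitter[sheet["animal_id"]].to_numpy()
    old_bacl2 = is_bacl2 & (sheet["age_group"] == "old").to_numpy()
    age_eff = chrono.copy()
    age_eff[old_bacl2] -= ck.regen_rejuvenation_rho * (
        chrono[old_bacl2] - ck.young_age_weeks
    )
    clock_beta = a0[:, None] + slope[:, None] * age_eff[None, :]
    if ck.noise_sd_beta > 0:
        clock_beta = clock_beta + rng.normal(0.0, ck.noise_sd_beta, clock_beta.shape)
    clock_beta = np.clip(clock_beta, 0.0, 1.0)
    clock_ids = [f"clk{j + 1:04d}" for j in range(n_ck)]
    clock_manifest = pd.DataFrame(
        {
            "probe_id": clock_ids,
            "chrom": "chr19",
            "pos": 60_000_000 + np.arange(n_ck) * 1_000,
            "gene_id": None,
            "feature_class": "intergenic",
            "tss_distance": 0,
        }
    )
    manifest = pd.concat([manifest, clock_manifest], ignore_index=True)
    all_vals = np.vstack([beta_vals, clock_beta])
    beta = BetaMatrix(
        pd.DataFrame(all_vals, index=manifest["probe_id"].tolist(), columns=sample_ids)
    )

    # exact least-squares inverse of the generative trend
    w = slope / np.sum(slope**2)
    clock = ClockModel(
        name="synthetic-generative",
        intercept=float(-np.sum(w * a0)),
        weights=dict(zip(clock_ids, w.astype(float))),
        gold_medians=dict(
            zip(clock_ids, np.median(clock_beta, axis=1).astype(float))
        ),
    )

    # --- RNA-seq counts ---------------------------------------------------
    log2_base_expr = rng.normal(6.0, 1.5, cfg.n_genes)
    lib = rng.uniform(*cfg.lib_size_range, n_samples)
    annotated = manifest.iloc[: len(beta_vals)]
    prom_man = annotated[annotated["feature_class"] == "promoter"]
    # per-gene mean promoter beta (observed) and its baseline
    gene_prom_beta = {}
    gene_prom_base = {}
    for gi, rows in prom_man.groupby("gene_id").groups.items():
        rows = np.asarray(rows)
        gene_prom_beta[gi] = beta_vals[rows].mean(axis=0)
        gene_prom_base[gi] = base[rows].mean()
    log2_mu = np.tile(log2_base_expr[:, None], (1, n_samples))
    coupling_sign = {}
    for gi in coupled_set:
        coupling_sign[gi] = 1
        gidx = int(gi[4:]) - 1
        loss = gene_prom_base[gi] - gene_prom_beta[gi]  # >0 under hypomethylation
        log2_mu[gidx] += cfg.coupling_gamma * loss
    mu = (2.0**log2_mu) * lib[None, :]
    if cfg.nb_dispersion > 0:
        nb_n = 1.0 / cfg.nb_dispersion
        counts = rng.negative_binomial(nb_n, nb_n / (nb_n + mu))
    else:
        counts = rng.poisson(mu)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)

    truth = GroundTruth(
        responsive_probes=pd.DataFrame(
            {
                "probe_id": manifest["probe_id"].iloc[resp_idx].to_numpy(),
                "gene_id": manifest["gene_id"].iloc[resp_idx].to_numpy(),
                "delta_beta_target": target - base[resp_idx],
                "logit_base": logit_base[resp_idx],
                "logit_shift_vehicle": shift_v,
                "logit_shift_senolytic": shift_s,
            }
        ),
        coupled_genes=pd.DataFrame(
            {"gene_id": sorted(coupled_set), "coupling_sign": [1] * len(coupled_set)}
        ),
        control_probes=[p for p in manifest["probe_id"] if p.startswith("ctl")],
        clock_probes=pd.DataFrame({"probe_id": clock_ids, "baseline": a0, "slope": slope}),
        true_clock=clock,
        true_ages=pd.Series(age_eff, index=sample_ids, name="age_weeks"),
        batch_effects=batch_eff,
        ruv_factor=ruv_factor,
        animal_intercepts=animal_eff,
    )
    return SimulatedStudy(
        manifest=manifest, beta=beta, counts=counts_df, sheet=sheet,
        genes=genes, clock=clock, truth=truth,
    )


def emit_de_table(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    arm: str = "OV",
    contrast: tuple[str, str, str] = ("limb", "BaCl2", "PBS"),
    min_mean_count: float = 10.0,
) -> pd.DataFrame:
    """Internal two-group DE test on log2 CPM, closing the synthetic loop.

    Stands on the moderated-t engine: per-gene OLS of log2 normalized
    counts (median-of-ratios size factors) on the contrast indicator,
    empirical-Bayes variance moderation, BH adjustment. Genes with
    all-zero counts in both groups are excluded (logged), as are weakly
    expressed genes
    below ``min_mean_count`` (independent filtering: without precision
    weights the log-scale variance of near-zero counts is badly behaved,
    so testing them costs calibration and multiple-testing power;
    ``min_mean_count=1`` effectively disables the filter).
    """
    from .diffmeth import (
        benjamini_hochberg, fit_probe_models, moderate_variances, moderated_t,
        DesignMatrix,
    )
    from .io import arm_samples

    sub = arm_samples(sheet, arm) if arm is not None else sheet
    col, lvl_a, lvl_b = contrast
    sel = sub[sub[col].isin([lvl_a, lvl_b])]
    for lvl in (lvl_a, lvl_b):
        if (sel[col] == lvl).sum() < 2:
            raise ValidationError(f"need >=2 samples with {col}={lvl}")
    mat = counts[sel["sample_id"].tolist()]
    zero = (mat.sum(axis=1) == 0)
    if zero.any():
        log.info("excluding %d gene(s) with all-zero counts", int(zero.sum()))
        mat = mat[~zero]
    if len(mat) > 1:
        weak = mat.mean(axis=1) < min_mean_count
        if weak.any():
            log.info("filtering %d weakly expressed gene(s)", int(weak.sum()))
            mat = mat[~weak]
    # median-of-ratios size factors (robust to asymmetric DE, where raw
    # library totals would shift every null gene's fold change)
    arr = mat.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    lib = arr.sum(axis=0)
    if positive.sum() >= 10:
        log_geo = np.log(arr[positive]).mean(axis=1)
        sf = np.exp(np.median(np.log(arr[positive]) - log_geo[:, None], axis=0))
    elif len(arr) >= 3 and lib.min() > 0:
        sf = lib / np.exp(np.mean(np.log(lib)))
    else:
        sf = np.ones(arr.shape[1])  # too few genes to normalize
    logcpm = pd.DataFrame(
        np.log2(arr / sf[None, :] + 0.5), index=mat.index, columns=mat.columns
    )

    X = pd.DataFrame(
        {
            "intercept": np.ones(len(sel)),
            "group": (sel[col] == lvl_a).to_numpy(dtype=float),
        },
        index=sel["sample_id"].tolist(),
    )
    design = DesignMatrix(
        sample_ids=sel["sample_id"].tolist(), X=X, contrast=np.array([0.0, 1.0])
    )
    holder = BetaMatrix.__new__(BetaMatrix)
    holder.values = logcpm
    fits = fit_probe_models(holder, design)
    if len(mat) >= 30:
        params, _ = moderate_variances(fits.s_sq, fits.df_resid)
    else:
        params = None
    _, p, _, _ = moderated_t(fits, params)
    q = benjamini_hochberg(p)
    return pd.DataFrame(
        {
            "gene_id": list(mat.index),
            "log2_fold_change": fits.effect,
            "p": p,
            "adj_p": q,
        }
    )
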