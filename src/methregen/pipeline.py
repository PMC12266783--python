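"""One-config orchestration: simulate -> DM -> peaks -> integration -> clocks -> stats.

A run is driven by a YAML config (or an equivalent dict) and writes an
append-only run directory: dm_<arm>.tsv, tally_<arm>.tsv, peaks_<arm>.bed,
de_<arm>.tsv, scores_<arm>.tsv, direction_tests.json, dnamage.tsv,
stats.json, report.md and a log. Outputs are stamped with the config
hash and seed; rerunning an identical config reproduces byte-identical
TSV/JSON outputs.

The single global seed is expanded into per-stage seeds with
``numpy.random.SeedSequence(seed).spawn`` in a fixed stage order
(simulate, de, direction_test), so stages stay individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clocks as clocks_mod
from . import diffmeth as dm_mod
from . import integration as integ_mod
from . import io as io_mod
from . import simulate as sim_mod
from . import studystats as stats_mod
from .io import ValidationError

log = logging.getLogger("methregen.pipeline")

_STAGE_ORDER = ("simulate", "de", "direction_test")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},  # SimulationConfig overrides; omit and set paths to use real inputs
    "paths": {},  # beta, sheet, manifest, genes, de, clock (used when simulate absent)
    "diffmeth": {
        "arms": ["OV"],
        "paired": True,
        "include_batch": True,
        "use_ruv": True,
        "use_m_values": False,
        "q_threshold": 0.05,
    },
    "integration": {
        "alpha": 0.5,
        "beta_decay": 4.0,
        "window_d": 100000,
        "de_adj_p_threshold": 0.05,
        "background_min_adj_p": 0.5,
        "rank_product_cutoff": 0.25,
        "direction_filter": "both",
        "n_permutations": 9999,
    },
    "clock": {"apply": True},
    "stats": {"anova_on_dnamage": True},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGE_ORDER))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(_STAGE_ORDER, children)
    }


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _preflight(config: dict) -> None:
    """Validate the config before anything is written."""
    if config.get("simulate") is None:
        paths = config.get("paths") or {}
        required = ["beta", "sheet", "manifest", "genes"]
        for key in required:
            p = paths.get(key)
            if p is None:
                raise ValidationError(f"config paths.{key} is required without a simulate block")
            if not Path(p).exists():
                raise ValidationError(f"config paths.{key}: file not found: {p}")


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> Path:
    """Execute the full chain; returns the run directory."""
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = _merge(DEFAULT_CONFIG, config)
    _preflight(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io_mod.setup_logging(outdir / "run.log")
    seed = int(config["seed"])
    seeds = _stage_seeds(seed)
    stamp = {"config_hash": _config_hash(config), "seed": seed}
    log.info("run start: %s", stamp)

    # --- stage: inputs ----------------------------------------------------
    de_tables: dict[str, pd.DataFrame] = {}
    if config.get("simulate") is not None:
        sim_cfg = sim_mod.SimulationConfig(
            **{**config["simulate"], "seed": config["simulate"].get("seed", seeds["simulate"])}
        )
        study = sim_mod.simulate_study(sim_cfg)
        manifest, beta, sheet, genes = study.manifest, study.beta, study.sheet, study.genes
        clock = study.clock
        io_mod.write_manifest(manifest, outdir / "manifest.tsv")
        io_mod.write_beta_matrix(beta, outdir / "beta.tsv")
        io_mod.write_sample_sheet(sheet, outdir / "sheet.tsv")
        io_mod.write_gene_models_bed(genes, outdir / "genes.bed")
        study.counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene_id")
        clocks_mod.write_clock(clock, outdir / "clock.tsv")
        study.truth.responsive_probes.to_csv(
            outdir / "ground_truth_responsive.tsv", sep="\t", index=False
        )
        counts = study.counts
        control_probes = study.truth.control_probes
    else:
        paths = config["paths"]
        beta = io_mod.read_beta_matrix(paths["beta"])
        sheet = io_mod.read_sample_sheet(paths["sheet"])
        manifest = io_mod.read_manifest(paths["manifest"])
        genes = io_mod.read_gene_models(paths["genes"])
        counts = None
        control_probes = None
        de_path = paths.get("de")
        if de_path:
            shared = io_mod.read_de_table(de_path)
            de_tables = {arm: shared for arm in config["diffmeth"]["arms"]}
        clock = clocks_mod.read_clock(paths["clock"]) if paths.get("clock") else None

    # --- stage: differential methylation + peaks + integration -----------
    dcfg = config["diffmeth"]
    icfg = config["integration"]
    params = integ_mod.RegulatoryPotentialParams(
        alpha=icfg["alpha"], beta_decay=icfg["beta_decay"], window_d=icfg["window_d"]
    )
    direction_results = {}
    for arm in dcfg["arms"]:
        model = dm_mod.DifferentialMethylation.from_study(
            beta,
            sheet,
            arm=arm,
            manifest=manifest,
            paired=dcfg["paired"],
            include_batch=dcfg["include_batch"],
            ruv=dcfg["use_ruv"],
            control_probes=control_probes,
            use_m_values=dcfg["use_m_values"],
        )
        res = model.fit()
        res.classify(dcfg["q_threshold"])
        res.records.to_csv(outdir / f"dm_{arm}.tsv", sep="\t", index=False, float_format="%.6g")
        res.tally_by_feature().to_csv(outdir / f"tally_{arm}.tsv", sep="\t")
        log.info("arm %s: %s", arm, res.summary().replace("\n", " | "))

        peaks = integ_mod.peaks_from_dm(
            res.records, manifest, q_threshold=dcfg["q_threshold"],
            direction_filter=icfg["direction_filter"],
        )
        io_mod.write_peaks_bed(peaks, outdir / f"peaks_{arm}.bed")

        if arm in de_tables:
            de = de_tables[arm]
        elif counts is not None:
            de = sim_mod.emit_de_table(counts, sheet, arm=arm)
        else:
            de = None
        if de is not None:
            io_mod.write_de_table(de, outdir / f"de_{arm}.tsv")
            rp = integ_mod.score_genes(genes, peaks, params)
            scores = integ_mod.rank_product_integration(
                rp, de,
                de_adj_p_threshold=icfg["de_adj_p_threshold"],
                rank_product_cutoff=icfg["rank_product_cutoff"],
            )
            scores.to_csv(outdir / f"scores_{arm}.tsv", sep="\t", index=False, float_format="%.6g")
            for label in ("up", "down"):
                try:
                    tr = integ_mod.direction_test(
                        rp, de, label,
                        de_adj_p_threshold=icfg["de_adj_p_threshold"],
                        background_min_adj_p=icfg["background_min_adj_p"],
                        n_permutations=icfg["n_permutations"],
                        seed=seeds["direction_test"],
                    )
                    direction_results[f"{arm}_{label}"] = tr.to_dict()
                except ValidationError as err:
                    log.warning("direction test %s/%s skipped: %s", arm, label, err)
    with open(outdir / "direction_tests.json", "w") as fh:
        json.dump({"stamp": stamp, "results": direction_results}, fh, indent=2, sort_keys=True)

    # --- stage: clocks + stats -------------------------------------------
    stats_out: dict = {}
    if config["clock"]["apply"] and clock is not None:
        ages = clocks_mod.apply_clock(beta, clock)
        ages = ages.merge(sheet, on="sample_id")
        ages.to_csv(outdir / "dnamage.tsv", sep="\t", index=False, float_format="%.6g")
        old = ages[ages["age_group"] == "old"]
        if config["stats"]["anova_on_dnamage"] and old["treatment"].nunique() == 2:
            tab = stats_mod.two_way_anova(
                old["dnam_age"], old["treatment"], old["limb"],
                names=("treatment", "injury"),
            )
            stats_out["anova_dnamage_old"] = {
                "ss_type": tab.ss_type,
                "p": {k: _nan_to_none(tab.table.loc[k, "p"]) for k in tab.table.index},
            }
        for arm in ("OV", "OS", "YV"):
            sub = ages.merge(io_mod.arm_samples(sheet, arm)[["sample_id"]], on="sample_id")
            if sub.empty:
                continue
            ctrl = sub[sub["limb"] == "PBS"]["dnam_age"].mean()
            trt = sub[sub["limb"] == "BaCl2"]["dnam_age"].mean()
            if ctrl > 0:
                dec = clocks_mod.percent_deceleration(ctrl, trt)
                stats_out[f"deceleration_{arm}"] = {
                    "mean_pbs_weeks": float(ctrl),
                    "mean_bacl2_weeks": float(trt),
                    "percent": dec.percent,
                    "weeks": dec.weeks,
                }
    with open(outdir / "stats.json", "w") as fh:
        json.dump({"stamp": stamp, "results": stats_out}, fh, indent=2, sort_keys=True)

    _write_report(outdir, config, stamp, dcfg["arms"], direction_results, stats_out)
    log.info("run complete: %s", outdir)
    return outdir


def _nan_to_none(v):
    v = float(v)
    return None if np.isnan(v) else v


def _write_report(outdir: Path, config, stamp, arms, direction_results, stats_out) -> None:
    lines = [
        "# Pipeline run report",
        "",
        f"- config hash: `{stamp['config_hash']}`",
        f"- seed: {stamp['seed']}",
        "",
        "## Differential methylation",
    ]
    for arm in arms:
        dm = pd.read_csv(outdir / f"dm_{arm}.tsv", sep="\t")
        n_sig = int((dm["direction"] != "ns").sum())
        n_peaks = sum(
            1 for line in open(outdir / f"peaks_{arm}.bed") if not line.startswith("#")
        )
        lines.append(f"- {arm}: {len(dm)} probes, {n_sig} significant (q<0.05), {n_peaks} peaks")
    lines += ["", "## Direction tests"]
    for key, res in sorted(direction_results.items()):
        lines.append(f"- {key}: D+={res['d_plus']:.4f}, p={res['p']:.4g} ({res['method']})")
    lines += ["", "## Clock / deceleration"]
    for key, res in sorted(stats_out.items()):
        lines.append(f"- {key}: {json.dumps(res, sort_keys=True)}")
    (outdir / "report.md").write_text("\n".join(lines) + "\n")
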