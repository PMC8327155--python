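"""Config-driven orchestration of the full synthetic-demo pipeline.

One YAML config file drives the chained stages
simulate -> authenticate -> bdtt -> diet -> copynumber, with a single
global seed from which every stage derives its own stream.  Each stage
writes plain TSV outputs into the run directory; a JSON manifest records
the seed, stage order and output checksums, so identical config + seed
reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import authenticity as auth
from . import bdtt as bdtt_mod
from . import copynumber as cn_mod
from . import diet as diet_mod
from .hosts import ecology_distance_matrix, read_host_meta, write_host_meta
from .io import read_abundance_table, write_abundance_table, \
    write_distance_matrix
from .simulate import (CommunitySimSpec, CoverageSimSpec, DamageSimSpec,
                       simulate_coverage, simulate_reads, simulate_scenario)
from .trees import cophenetic_distances, read_calibrated_tree

logger = logging.getLogger(__name__)

STAGES = ("simulate", "authenticate", "bdtt", "diet", "copynumber")

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "STAGES"]


@dataclass
class PipelineConfig:
    seed: int
    outdir: Path
    stages: tuple = STAGES
    community: dict = field(default_factory=dict)
    damage: dict = field(default_factory=dict)
    coverage: dict = field(default_factory=dict)
    bdtt: dict = field(default_factory=lambda: {
        "n_ages": 6, "n_perm": 199, "n_shuffles": 199})
    screening: dict = field(default_factory=dict)
    diet: dict = field(default_factory=lambda: {
        "alpha": 0.05, "threshold": 0.5, "n_perm": 199, "cv": True})
    copynumber: dict = field(default_factory=lambda: {
        "anchor_group": "wolf", "anchor_cn": 2.0, "level": 0.95})

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}")
        alpha = self.diet.get("alpha", 0.05)
        if not (0.0 < alpha <= 1.0):
            raise ValueError(f"alpha out of range (0, 1]: {alpha}")
        thr = self.diet.get("threshold", 0.5)
        if not (0.0 < thr < 1.0):
            raise ValueError(f"threshold out of range (0, 1): {thr}")
        level = self.copynumber.get("level", 0.95)
        if not (0.0 < level < 1.0):
            raise ValueError(f"confidence level out of range (0, 1): {level}")
        if self.seed is None:
            raise ValueError("a global seed is mandatory")


def validate_config(path) -> PipelineConfig:
    """Parse and cross-check a YAML pipeline config; echo it to the log."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ValueError("config must set 'seed'")
    if "outdir" not in raw:
        raise ValueError("config must set 'outdir'")
    known = {f.name for f in PipelineConfig.__dataclass_fields__.values()}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    if "simulate" not in cfg.stages:
        for name in ("tree.nwk", "host_tree.nwk", "abundance.tsv",
                     "hosts.tsv"):
            p = cfg.outdir / name
            if any(s in cfg.stages for s in ("bdtt", "diet")) and not p.exists():
                raise ValueError(f"required input missing: {p}")
    logger.info("resolved config: %s", cfg)
    return cfg


def _sub_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31)
            for s in np.random.SeedSequence(seed).spawn(n)]


def _stage_simulate(cfg: PipelineConfig, seeds: dict) -> None:
    spec = CommunitySimSpec(**{**cfg.community, "seed": seeds["simulate"]})
    tree, host_tree, table, meta = simulate_scenario(spec)
    tree.write(cfg.outdir / "tree.nwk")
    host_tree.write(cfg.outdir / "host_tree.nwk")
    write_abundance_table(table, cfg.outdir / "abundance.tsv")
    write_host_meta(diet_mod.default_canid_diets(meta),
                    cfg.outdir / "hosts.tsv")
    reads = simulate_reads(DamageSimSpec(
        **{**cfg.damage, "seed": seeds["simulate"] + 1}))
    auth.write_records_tsv(reads, cfg.outdir / "reads.tsv")
    counts = simulate_coverage(CoverageSimSpec(
        **{**cfg.coverage, "seed": seeds["simulate"] + 2}))
    cn_mod.write_region_counts(counts, cfg.outdir / "region_counts.tsv")


def _stage_authenticate(cfg: PipelineConfig, seeds: dict) -> None:
    rules = auth.ScreeningRules(**cfg.screening) if cfg.screening \
        else auth.BACTERIAL_RULES
    published = auth.load_solarolo_bacterial_table()
    auth.screen_table(published, rules).to_csv(
        cfg.outdir / "screen_bacterial.tsv", sep="\t", index=False)
    auth.screen_table(auth.load_solarolo_dietary_table(),
                      auth.DIETARY_RULES).to_csv(
        cfg.outdir / "screen_dietary.tsv", sep="\t", index=False)
    reads_path = cfg.outdir / "reads.tsv"
    if reads_path.exists():
        reads = auth.read_records_tsv(reads_path)
        profile = auth.fit_damage_profile(reads)
        pd.DataFrame({"position": np.arange(1, auth.N_POSITIONS + 1),
                      "ct_rate": profile.rates,
                      "c_sites": profile.c_sites}).to_csv(
            cfg.outdir / "damage_profile.tsv", sep="\t", index=False)
        summary = auth.summarize_reads("simulated_taxon", reads)
        auth.screen_table([summary], rules).to_csv(
            cfg.outdir / "screen_simulated.tsv", sep="\t", index=False)


def _load_hosts_inputs(cfg: PipelineConfig):
    tree = read_calibrated_tree(cfg.outdir / "tree.nwk")
    host_tree = read_calibrated_tree(cfg.outdir / "host_tree.nwk")
    table = read_abundance_table(cfg.outdir / "abundance.tsv")
    meta = read_host_meta(cfg.outdir / "hosts.tsv")
    return tree, host_tree, table, meta


def _stage_bdtt(cfg: PipelineConfig, seeds: dict) -> None:
    tree, host_tree, table, meta = _load_hosts_inputs(cfg)
    host_ids = [m.host_id for m in meta]
    factors = {
        "phylogeny": cophenetic_distances(host_tree).filter(host_ids),
        "ecology": ecology_distance_matrix(meta),
    }
    opts = cfg.bdtt
    ages = opts.get("ages") or list(
        np.linspace(0, tree.depth, int(opts.get("n_ages", 6))))
    profile = bdtt_mod.bdtt_profile(
        tree, table, factors, ages,
        n_perm=int(opts.get("n_perm", 199)),
        n_shuffles=int(opts.get("n_shuffles", 199)), seed=seeds["bdtt"])
    profile.to_frame().to_csv(cfg.outdir / "bdtt_profile.tsv", sep="\t",
                              index=False)
    for name, dm in factors.items():
        write_distance_matrix(dm, cfg.outdir / f"factor_{name}.tsv")
    mid_ages = ages[1:-1] if len(ages) > 2 else ages
    tables = {a: bdtt_mod.collapse_table(table, bdtt_mod.slice_tree(tree, a))
              for a in mid_ages}
    hits = bdtt_mod.lineage_association(
        tables, factors, n_perm=int(opts.get("n_perm", 199)),
        seed=seeds["bdtt"] + 1)
    hits.to_csv(cfg.outdir / "lineage_hits.tsv", sep="\t", index=False)


def _stage_diet(cfg: PipelineConfig, seeds: dict) -> None:
    tree, _, table, meta = _load_hosts_inputs(cfg)
    # the dietary analysis operates on bacterial lineages: collapse the
    # taxon table onto clades at a mid-depth slice before selection
    slice_age = float(cfg.diet.get("slice_age", 0.5) * tree.depth) \
        if cfg.diet.get("slice_age", 0.5) <= 1 else float(cfg.diet["slice_age"])
    table = bdtt_mod.collapse_table(table,
                                    bdtt_mod.slice_tree(tree, slice_age))
    meta = diet_mod.default_canid_diets(meta)
    labels = diet_mod.labels_from_meta(meta)
    modern = [m.host_id for m in meta if m.group in ("wolf", "dog")]
    ancient = [m.host_id for m in meta if m.group == "ancient"]
    diet_dm = diet_mod.diet_distance(meta)
    opts = cfg.diet
    sel = diet_mod.select_diet_taxa(
        table.loc[modern], diet_dm, alpha=float(opts.get("alpha", 0.05)),
        n_perm=int(opts.get("n_perm", 199)), seed=seeds["diet"])
    if not sel:
        raise RuntimeError("diet stage: no diet-correlated taxa retained")
    model = diet_mod.fit_diet_model(table.loc[modern, sel],
                                    {h: labels[h] for h in modern},
                                    threshold=float(opts.get("threshold", 0.5)))
    rows = [{"host": h, "group": "ancient",
             **dict(zip(("prob_omnivorous", "predicted"),
                        diet_mod.predict_diet(model, table.loc[h])))}
            for h in ancient]
    pd.DataFrame(rows).to_csv(cfg.outdir / "diet_predictions.tsv", sep="\t",
                              index=False)
    pd.DataFrame({"taxon": sel}).to_csv(cfg.outdir / "diet_taxa.tsv",
                                        sep="\t", index=False)
    if opts.get("cv", True):
        acc, record = diet_mod.cross_validate(
            table.loc[modern], labels, diet_dm,
            alpha=float(opts.get("alpha", 0.05)),
            n_perm=int(opts.get("n_perm", 199)), seed=seeds["diet"] + 1)
        record.to_csv(cfg.outdir / "diet_cv.tsv", sep="\t", index=False)
        (cfg.outdir / "diet_cv_accuracy.txt").write_text(f"{acc:.6f}\n")


def _stage_copynumber(cfg: PipelineConfig, seeds: dict) -> None:
    counts = cn_mod.read_region_counts(cfg.outdir / "region_counts.tsv")
    opts = cfg.copynumber
    cn_mod.estimate_copy_numbers(
        counts, anchor_group=opts.get("anchor_group", "wolf"),
        anchor_copy_number=float(opts.get("anchor_cn", 2.0)),
        level=float(opts.get("level", 0.95))).to_csv(
        cfg.outdir / "copy_numbers.tsv", sep="\t", index=False)


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "authenticate": _stage_authenticate,
    "bdtt": _stage_bdtt,
    "diet": _stage_diet,
    "copynumber": _stage_copynumber,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the enabled stages in canonical order; write a run manifest.

    Returns the manifest dict.  On stage failure, partial outputs are kept
    and the manifest records the failure point before the exception is
    re-raised.
    """
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    stage_seeds = dict(zip(STAGES, _sub_seeds(cfg.seed, len(STAGES))))
    manifest = {"seed": cfg.seed, "stages": [], "outputs": {},
                "failed_stage": None}
    try:
        for stage in STAGES:
            if stage not in cfg.stages:
                continue
            logger.info("stage %s starting", stage)
            try:
                _STAGE_FNS[stage](cfg, stage_seeds)
            except Exception:
                manifest["failed_stage"] = stage
                raise
            manifest["stages"].append(stage)
            logger.info("stage %s done", stage)
    finally:
        for p in sorted(cfg.outdir.glob("*.tsv")) + \
                sorted(cfg.outdir.glob("*.nwk")):
            manifest["outputs"][p.name] = hashlib.sha256(
                p.read_bytes()).hexdigest()
        with open(cfg.outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
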