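"""End-to-end orchestration: simulate -> call -> consensus -> densities and
profiles -> clusters -> sex comparisons, driven by one YAML-style config.

Each stage records its parameters and the SHA-256 of every file it writes
in a manifest, so a rerun with the same config can be verified
byte-for-byte. A single global seed feeds per-stage child seeds by a
stable derivation, keeping stages individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io
from .calling import CallerConfig, call_sites, collapse_duplicates, filter_reads
from .clusters import ClusterConfig, assign_cluster_gene, call_clusters
from .consensus import StringencyConfig, build_consensus, stringency_subset
from .datamodel import CpgIndex, Genome
from .density import (
    ExpressionTable,
    chromosome_density,
    exon_boundary_profile,
    feature_density,
    metagene_profile,
    peak_profile,
)
from .sexdiff import SexConfig, escape_density, female_unique_sites, male_specific_clusters
from .simulate import SimConfig, make_annotations, make_genome, plant_truth, simulate_reads

log = logging.getLogger(__name__)

__all__ = ["load_config", "run_pipeline"]

ALL_STAGES = ["simulate", "call", "consensus", "density", "profiles", "clusters", "sexdiff"]


def load_config(path: str | Path) -> dict:
    with open(path) as handle:
        config = yaml.safe_load(handle)
    if not isinstance(config, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return config


def _child_seed(seed: int, stage_index: int) -> int:
    return (seed * 1_000_003 + stage_index) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_hash(params: dict) -> str:
    return hashlib.sha256(json.dumps(params, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: dict | str | Path, outdir: Optional[str | Path] = None) -> dict:
    """Run the configured stages in dependency order; return the manifest.

    The config needs an ``outdir`` (unless passed explicitly), a global
    ``seed``, and per-stage blocks: ``simulate`` (SimConfig fields plus
    ``n_females``/annotation options), ``caller``, ``stringency`` (with
    ``tier``), ``cluster``, ``sex``, ``profiles``. A ``stages`` list
    restricts which stages run; later stages are skipped automatically
    when their inputs were not produced.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir or config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", ALL_STAGES)
    manifest: dict = {"seed": seed, "stages": []}
    state: dict = {}

    def record(stage: str, params: dict, outputs: dict[str, Path]):
        manifest["stages"].append(
            {
                "stage": stage,
                "params_hash": _params_hash(params),
                "outputs": {name: {"path": str(p), "sha256": _sha256(p)} for name, p in outputs.items()},
            }
        )

    try:
        if "simulate" in stages and "simulate" in config:
            _stage_simulate(config, outdir, seed, state, record)
        else:
            _load_inputs(config, state)
        if "call" in stages and state.get("reads"):
            _stage_call(config, outdir, state, record)
        if "consensus" in stages and state.get("sitesets"):
            _stage_consensus(config, outdir, state, record)
        if "density" in stages and state.get("consensus_sites") is not None:
            _stage_density(config, outdir, state, record)
        if "profiles" in stages and state.get("consensus_sites") is not None and state.get("genes"):
            _stage_profiles(config, outdir, state, record)
        if "clusters" in stages and state.get("consensus_sites") is not None:
            _stage_clusters(config, outdir, state, record)
        if "sexdiff" in stages and state.get("sitesets"):
            _stage_sexdiff(config, outdir, seed, state, record)
    except Exception as exc:
        stage = manifest["stages"][-1]["stage"] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline aborted after stage {stage!r}: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as out:
        json.dump(manifest, out, indent=2, sort_keys=True)
    return manifest


def _stage_simulate(config, outdir, seed, state, record):
    block = dict(config["simulate"])
    n_females = int(block.pop("n_females", 0))
    annot_opts = block.pop("annotations", {}) or {}
    sim_cfg = SimConfig(**block, seed=_child_seed(seed, 0))
    sim_dir = outdir / "sim"
    (sim_dir / "truth").mkdir(parents=True, exist_ok=True)
    (sim_dir / "reads").mkdir(exist_ok=True)
    (sim_dir / "annotations").mkdir(exist_ok=True)

    genome = make_genome(sim_cfg)
    truth = plant_truth(genome, sim_cfg)
    outputs = {"genome": io.write_genome(genome, sim_dir / "genome.fa")}
    for i, ss in enumerate(truth.individuals):
        ss.sex = "F" if i < n_females else "M"
        outputs[f"truth_{ss.individual_id}"] = io.write_sites(
            sim_dir / "truth" / f"{ss.individual_id}.bed", ss
        )
        sam = sim_dir / "reads" / f"{ss.individual_id}.sam"
        simulate_reads(genome, ss, sim_cfg, sam, rng=np.random.default_rng(_child_seed(seed, 100 + i)))
        outputs[f"reads_{ss.individual_id}"] = sam

    features, genes, expr, escape = make_annotations(genome, seed=_child_seed(seed, 1), **annot_opts)
    by_kind: dict[str, list] = {}
    for f in features:
        by_kind.setdefault(f.kind, []).append(f)
    for kind, feats in by_kind.items():
        outputs[f"features_{kind}"] = io.write_features(feats, sim_dir / "annotations" / f"{kind}.bed")
    outputs["genes"] = io.write_gene_models(genes, sim_dir / "annotations" / "genes.tsv")
    expr.to_csv(sim_dir / "expression.tsv", sep="\t", index=False)
    outputs["expression"] = sim_dir / "expression.tsv"
    escape.to_csv(sim_dir / "escape.tsv", sep="\t", index=False)
    outputs["escape"] = sim_dir / "escape.tsv"
    meta = pd.DataFrame(
        {"individual_id": [ss.individual_id for ss in truth.individuals],
         "sex": [ss.sex for ss in truth.individuals]}
    )
    meta.to_csv(sim_dir / "metadata.tsv", sep="\t", index=False)
    outputs["metadata"] = sim_dir / "metadata.tsv"

    state.update(
        genome=genome,
        cpg_index=CpgIndex.from_genome(genome),
        truth=truth,
        reads=[(ss.individual_id, ss.sex, sim_dir / "reads" / f"{ss.individual_id}.sam") for ss in truth.individuals],
        features=features,
        genes=genes,
        expression=expr,
        escape=dict(zip(escape["gene_id"], escape["score"].astype(int))),
    )
    record("simulate", {**asdict(sim_cfg), "n_females": n_females}, outputs)


def _load_inputs(config, state):
    paths = config.get("paths", {})
    if "genome" in paths:
        genome = io.load_genome(paths["genome"])
        state.update(genome=genome, cpg_index=CpgIndex.from_genome(genome))
    if "reads" in paths:
        meta = pd.read_csv(paths["metadata"], sep="\t") if "metadata" in paths else None
        reads = []
        for sam in sorted(Path(paths["reads"]).glob("*.sam")):
            sex = "U"
            if meta is not None:
                row = meta.loc[meta["individual_id"] == sam.stem, "sex"]
                sex = str(row.iloc[0]) if len(row) else "U"
            reads.append((sam.stem, sex, sam))
        state["reads"] = reads
    if "annotations" in paths:
        feature_paths = {
            p.stem: p for p in sorted(Path(paths["annotations"]).glob("*.bed"))
        }
        gene_path = Path(paths["annotations"]) / "genes.tsv"
        features, genes = io.load_annotations(
            feature_paths, gene_path if gene_path.exists() else None, state.get("genome")
        )
        state.update(features=features, genes=genes)
    if "expression" in paths:
        state["expression"] = io.read_expression(paths["expression"])
    if "escape" in paths:
        state["escape"] = io.read_escape(paths["escape"])


def _stage_call(config, outdir, state, record):
    cfg = CallerConfig(**config.get("caller", {}))
    sites_dir = outdir / "sites"
    sites_dir.mkdir(exist_ok=True)
    sitesets = []
    outputs = {}
    for individual_id, sex, sam in state["reads"]:
        reads = io.read_alignments(sam, state["genome"])
        reads = filter_reads(reads, cfg)
        if cfg.collapse_duplicates:
            reads = collapse_duplicates(sorted(reads, key=lambda r: (r.chrom, r.start, r.strand)))
        ss = call_sites(reads, state["genome"], cfg, individual_id=individual_id, sex=sex)
        sitesets.append(ss)
        outputs[individual_id] = io.write_sites(sites_dir / f"{individual_id}.bed", ss)
    state["sitesets"] = sitesets
    record("call", asdict(cfg), outputs)


def _stage_consensus(config, outdir, state, record):
    block = dict(config.get("stringency", {}))
    tier = block.pop("tier", "intermediate")
    cfg = StringencyConfig(**block) if block else StringencyConfig()
    table = build_consensus(state["sitesets"])
    subset = stringency_subset(table, tier=tier, cfg=cfg)
    cons_dir = outdir / "consensus"
    cons_dir.mkdir(exist_ok=True)
    outputs = {"consensus": io.write_sites(cons_dir / "consensus.bed", subset)}
    sharing = pd.DataFrame(
        {
            "min_count": range(1, table.n_individuals + 1),
            "fraction": [table.sharing_fraction(k) for k in range(1, table.n_individuals + 1)],
        }
    )
    sharing.to_csv(cons_dir / "sharing.tsv", sep="\t", index=False)
    outputs["sharing"] = cons_dir / "sharing.tsv"
    state["consensus_table"] = table
    state["consensus_sites"] = subset
    record("consensus", {"tier": tier, "fractions": cfg.fractions}, outputs)


def _stage_density(config, outdir, state, record):
    dens_dir = outdir / "density"
    dens_dir.mkdir(exist_ok=True)
    chrom = chromosome_density(state["consensus_sites"], state["genome"], state["cpg_index"])
    df = pd.DataFrame([vars(r) for r in chrom])
    df.to_csv(dens_dir / "chromosome_density.tsv", sep="\t", index=False)
    outputs = {"chromosome": dens_dir / "chromosome_density.tsv"}
    if state.get("features"):
        feats = feature_density(state["consensus_sites"], state["features"], state["cpg_index"])
        pd.DataFrame([vars(r) for r in feats]).to_csv(
            dens_dir / "feature_density.tsv", sep="\t", index=False
        )
        outputs["features"] = dens_dir / "feature_density.tsv"
    record("density", {}, outputs)


def _stage_profiles(config, outdir, state, record):
    block = config.get("profiles", {})
    prof_dir = outdir / "profiles"
    prof_dir.mkdir(exist_ok=True)
    outputs = {}
    sites = state["consensus_sites"]
    peaks = [f for f in state.get("features", []) if f.kind == "chip_peak"]
    if peaks:
        pm = peak_profile(
            sites, peaks, block.get("peak_half_window", 3000), block.get("peak_bin", 100)
        )
        pm.to_frame().to_csv(prof_dir / "peak_profile.tsv", sep="\t", index=False)
        outputs["peak"] = prof_dir / "peak_profile.tsv"
    if state.get("expression") is not None:
        expr = ExpressionTable.from_frame(state["expression"])
        profiles = metagene_profile(
            sites,
            state["genes"],
            expr,
            flank=block.get("metagene_flank", 20_000),
            nbins=block.get("metagene_nbins", 50),
        )
        frames = []
        for q, pm in profiles.items():
            frame = pm.to_frame()
            frame["quartile"] = q
            frames.append(frame)
        pd.concat(frames).to_csv(prof_dir / "metagene_profile.tsv", sep="\t", index=False)
        outputs["metagene"] = prof_dir / "metagene_profile.tsv"
    sense, antisense = exon_boundary_profile(sites, state["genes"], block.get("boundary_flank", 20))
    for name, pm in (("sense", sense), ("antisense", antisense)):
        pm.to_frame().to_csv(prof_dir / f"boundary_{name}.tsv", sep="\t", index=False)
        outputs[f"boundary_{name}"] = prof_dir / f"boundary_{name}.tsv"
    record("profiles", dict(block), outputs)


def _stage_clusters(config, outdir, state, record):
    cfg = ClusterConfig(**config.get("cluster", {}))
    clus_dir = outdir / "clusters"
    clus_dir.mkdir(exist_ok=True)
    clusters = call_clusters(state["consensus_sites"], cfg)
    if state.get("genes"):
        clusters = [assign_cluster_gene(c, state["genes"], cfg) for c in clusters]
    pd.DataFrame([vars(c) for c in clusters]).to_csv(
        clus_dir / "clusters.tsv", sep="\t", index=False
    )
    state["clusters"] = clusters
    record("clusters", asdict(cfg), {"clusters": clus_dir / "clusters.tsv"})


def _stage_sexdiff(config, outdir, seed, state, record):
    block = dict(config.get("sex", {}))
    block.pop("n_females", None)
    sex_cfg = SexConfig(**{**block, "seed": block.get("seed", _child_seed(seed, 7))})
    females = [ss for ss in state["sitesets"] if ss.sex == "F"]
    males = [ss for ss in state["sitesets"] if ss.sex == "M"]
    if not females or not males:
        log.info("sexdiff: need both sexes; skipping")
        return
    sd_dir = outdir / "sexdiff"
    sd_dir.mkdir(exist_ok=True)
    outputs = {}
    fu = female_unique_sites(females, males)
    outputs["female_unique"] = io.write_sites(sd_dir / "female_unique.bed", fu)
    if len(males) >= sex_cfg.male_set_size:
        cluster_cfg = ClusterConfig(**config.get("cluster", {}))
        msc = male_specific_clusters(males, females, cluster_cfg, sex_cfg)
        pd.DataFrame([vars(c) for c in msc]).to_csv(
            sd_dir / "male_specific_clusters.tsv", sep="\t", index=False
        )
        outputs["male_specific_clusters"] = sd_dir / "male_specific_clusters.tsv"
    escape = state.get("escape")
    if escape and state.get("genes"):
        scored = [g for g in state["genes"] if g.gene_id in escape]
        if scored:
            per_gene, groups, test = escape_density(
                females, scored, escape, state["cpg_index"]
            )
            per_gene.to_csv(sd_dir / "escape_density.tsv", sep="\t", index=False)
            with open(sd_dir / "escape_test.json", "w") as out:
                json.dump(test, out, indent=2)
            outputs["escape_density"] = sd_dir / "escape_density.tsv"
            outputs["escape_test"] = sd_dir / "escape_test.json"
    record("sexdiff", {**asdict(sex_cfg)}, outputs)
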