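"""End-to-end pipeline orchestration with a single seeded configuration.

Stages run in order: simulate -> preprocess -> detect -> diff -> patterns
-> enrich -> modules -> qpcr, each reading only upstream artifacts and
writing its own files plus a manifest entry (row counts and SHA-256 file
hashes), so a fixed seed and config reproduce every file byte-identically.
Threshold defaults are the source procedure's stated values (filter 30,
K=15, m=0.44, assignment r=0.85, q<0.05, |FC|>=2, enrichment p<0.001).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .containers import ExpressionMatrix
from .detection import consensus_present, detection_calls
from .differential import Contrast, diff_test, select_deg
from .enrichment import go_enrichment, log10_matrix, motif_enrichment, motif_hit_table
from .modules import build_module, export_cytoscape, graph_to_json
from .patterns import dominant_patterns
from .preprocess import bootstrap_hclust, replicate_correlation, rma_summarize
from .qpcr import ddct_table
from .simulate import (
    AnnotationConfig,
    StudyDesign,
    TruthConfig,
    generate_annotations,
    generate_probe_intensities,
    generate_qpcr_table,
)

ALL_STAGES = ("simulate", "preprocess", "detect", "diff", "patterns",
              "enrich", "modules", "qpcr")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; defaults are the study conditions."""

    outdir: str = "pipeline_out"
    seed: int = 0
    # design
    genotypes: tuple[str, ...] = ("WT", "vtc2")
    stages: tuple[str, ...] = ("bent_cotyledon", "D7I", "D14I", "mature_SE")
    replicates_per_cell: int = 2
    n_genes: int = 500
    n_probes_per_set: int = 11
    # generator noise / truth
    n_patterns: int = 6
    genes_per_pattern: int = 50
    genotype_symmetric_patterns: bool = True
    de_effect: float = 3.0
    n_de_up_per_stage: int = 12
    n_de_down_per_stage: int = 8
    n_absent_genes: int = 50
    probe_noise_sd: float = 0.2
    replicate_sd: float = 0.15
    # thresholds (the procedure's stated defaults)
    expression_filter: float = 30.0
    k: int = 15
    m: float = 0.44
    assign_r: float = 0.85
    merge_r: float = 0.90
    q_threshold: float = 0.05
    fc_threshold: float = 2.0
    enrich_p: float = 0.001
    # detection
    tau: float = 0.015
    alpha1: float = 0.04
    alpha2: float = 0.06
    # misc
    n_boot: int = 50
    run_stages: tuple[str, ...] = ALL_STAGES

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("genotypes", "stages", "run_stages"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        errors = validate_config(cfg)
        if errors:
            raise ValueError("; ".join(errors))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("genotypes", "stages", "run_stages"):
            d[key] = list(d[key])
        return d


def validate_config(cfg: RunConfig) -> list[str]:
    """Range-check every threshold; an empty list means the config is valid."""
    errors = []
    if cfg.k < 2:
        errors.append("k must be >= 2")
    if not 0 < cfg.m <= 1:
        errors.append("m must be in (0, 1]")
    for name in ("assign_r", "merge_r"):
        v = getattr(cfg, name)
        if not -1 <= v <= 1:
            errors.append(f"{name} must be a correlation in [-1, 1]")
    if not 0 < cfg.q_threshold < 1:
        errors.append("q_threshold must be in (0, 1)")
    if cfg.fc_threshold < 1:
        errors.append("fc_threshold must be >= 1")
    if not 0 < cfg.enrich_p < 1:
        errors.append("enrich_p must be in (0, 1)")
    if cfg.expression_filter < 0:
        errors.append("expression_filter must be >= 0")
    if not 0 < cfg.alpha1 < cfg.alpha2 < 0.5:
        errors.append("need 0 < alpha1 < alpha2 < 0.5")
    if cfg.n_genes < 1:
        errors.append("n_genes must be >= 1")
    if cfg.replicates_per_cell < 2:
        errors.append("replicates_per_cell must be >= 2")
    if cfg.n_boot < 1:
        errors.append("n_boot must be >= 1")
    unknown_stages = set(cfg.run_stages) - set(ALL_STAGES)
    if unknown_stages:
        errors.append(f"unknown stages: {sorted(unknown_stages)}")
    return errors


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in order; returns the manifest dict.

    A stage failure aborts the run with the failing stage named; files
    written before the failure keep a ``.partial`` marker next to them.
    """
    errors = validate_config(cfg)
    if errors:
        raise ValueError("; ".join(errors))
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.to_dict(), "stages": {}, "files": {}}
    written: list[Path] = []

    def record(stage: str, paths: dict[str, Path], counts: dict):
        manifest["stages"][stage] = {"counts": counts}
        for name, p in paths.items():
            manifest["files"][f"{stage}/{name}"] = _sha256(Path(p))
            written.append(Path(p))

    state: dict = {}
    stage = "<setup>"
    try:
        for stage in ALL_STAGES:
            if stage not in cfg.run_stages:
                continue
            _STAGE_FUNCS[stage](cfg, out, state, record)
    except Exception as exc:
        marker = out / "FAILED.partial"
        marker.write_text(f"failed stage: {stage}\n{exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


# --------------------------------------------------------------------------
# stage implementations
# --------------------------------------------------------------------------

def _stage_simulate(cfg, out, state, record):
    design = StudyDesign(
        genotypes=tuple(cfg.genotypes), stages=tuple(cfg.stages),
        replicates_per_cell=cfg.replicates_per_cell, n_genes=cfg.n_genes,
        n_probes_per_set=cfg.n_probes_per_set, seed=cfg.seed,
    )
    truth_cfg = TruthConfig(
        n_patterns=cfg.n_patterns, genes_per_pattern=cfg.genes_per_pattern,
        genotype_symmetric_patterns=cfg.genotype_symmetric_patterns,
        de_effect=cfg.de_effect, n_de_up_per_stage=cfg.n_de_up_per_stage,
        n_de_down_per_stage=cfg.n_de_down_per_stage,
        n_absent_genes=cfg.n_absent_genes,
        probe_noise_sd=cfg.probe_noise_sd, replicate_sd=cfg.replicate_sd,
    )
    dataset = generate_probe_intensities(design, truth_cfg)
    annotations = generate_annotations(dataset)
    io.write_probe_table(dataset.probes, out / "probes.tsv")
    io.write_sample_sheet(design.sample_sheet(), out / "samples.csv")
    io.write_json(dataset.truth.to_dict(), out / "truth.json")
    io.write_gmt(annotations["gmt"], out / "terms.gmt")
    io.write_fasta(annotations["promoters"], out / "promoters.fasta")
    io.write_motif_table(annotations["motifs"], out / "motifs.tsv")
    io.write_tf_map(annotations["tf_map"], out / "tf_map.tsv")
    state["dataset"] = dataset
    state["annotations"] = annotations
    record("simulate", {
        "probes": out / "probes.tsv", "samples": out / "samples.csv",
        "truth": out / "truth.json", "gmt": out / "terms.gmt",
        "promoters": out / "promoters.fasta", "motifs": out / "motifs.tsv",
        "tf_map": out / "tf_map.tsv",
    }, {"n_genes": design.n_genes, "n_samples": design.n_samples})


def _stage_preprocess(cfg, out, state, record):
    if "dataset" in state:
        probes = state["dataset"].probes
    else:
        probes = io.read_probe_table(out / "probes.tsv", out / "samples.csv")
    matrix = rma_summarize(probes)
    io.write_expression_matrix(matrix, out / "expression.tsv")
    qc = replicate_correlation(matrix)
    qc.to_csv(out / "replicate_qc.csv", index=False)
    tree = bootstrap_hclust(matrix, n_boot=cfg.n_boot, seed=cfg.seed + 1)
    (out / "samples.nwk").write_text(tree.to_newick() + "\n")
    state["matrix"] = matrix
    record("preprocess", {
        "expression": out / "expression.tsv",
        "qc": out / "replicate_qc.csv", "tree": out / "samples.nwk",
    }, {"n_genes": matrix.n_genes, "mean_replicate_r": float(qc["r"].mean())})


def _stage_detect(cfg, out, state, record):
    if "dataset" in state:
        probes = state["dataset"].probes
    else:
        probes = io.read_probe_table(out / "probes.tsv", out / "samples.csv")
    calls = detection_calls(probes, tau=cfg.tau, alpha1=cfg.alpha1,
                            alpha2=cfg.alpha2)
    calls.to_csv(out / "detection_calls.tsv", sep="\t", index=False)
    consensus, counts = consensus_present(calls, probes.samples)
    consensus.rename_axis("gene").to_csv(out / "detection_consensus.tsv", sep="\t")
    state["consensus"] = consensus
    record("detect", {
        "calls": out / "detection_calls.tsv",
        "consensus": out / "detection_consensus.tsv",
    }, {"detected_per_tissue": {k: int(v) for k, v in counts.items()}})


def _get_matrix(out, state) -> ExpressionMatrix:
    if "matrix" not in state:
        state["matrix"] = io.read_expression_matrix(
            out / "expression.tsv", out / "samples.csv"
        )
    return state["matrix"]


def _stage_diff(cfg, out, state, record):
    matrix = _get_matrix(out, state)
    genotype_a, genotype_b = cfg.genotypes[0], cfg.genotypes[1]
    summary = {}
    results = {}
    paths = {}
    for stage_name in cfg.stages:
        contrast = Contrast(stage_name, genotype_a, genotype_b)
        result = diff_test(matrix, contrast, q_threshold=cfg.q_threshold,
                           fc_threshold=cfg.fc_threshold)
        path = out / f"diff_{stage_name}.tsv"
        result.rename_axis("gene").to_csv(path, sep="\t")
        deg = select_deg(result, fc_threshold=cfg.fc_threshold)
        summary[stage_name] = {"n_up": deg["n_up"], "n_down": deg["n_down"]}
        results[stage_name] = result
        paths[stage_name] = path
    io.write_json(summary, out / "diff_summary.json")
    paths["summary"] = out / "diff_summary.json"
    state["diff"] = results
    record("diff", paths, summary)


def _stage_patterns(cfg, out, state, record):
    matrix = _get_matrix(out, state)
    patterns, partition, profiles = dominant_patterns(
        matrix, k=cfg.k, m=cfg.m, assign_r=cfg.assign_r, merge_r=cfg.merge_r,
        expression_threshold=cfg.expression_filter, seed=cfg.seed + 2,
    )
    partition.membership.rename_axis("gene").to_csv(
        out / "membership.tsv", sep="\t")
    patterns.prototypes.rename_axis("pattern").to_csv(
        out / "prototypes.tsv", sep="\t")
    patterns.assignments.rename_axis("gene").to_csv(
        out / "assignments.tsv", sep="\t")
    sizes = {k: int(v) for k, v in patterns.pattern_sizes().items()}
    io.write_json(sizes, out / "pattern_sizes.json")
    long = patterns.prototypes.rename_axis("pattern").reset_index().melt(
        id_vars="pattern", var_name="cell", value_name="level")
    long.to_csv(out / "prototypes_long.csv", index=False)
    state["patterns"] = patterns
    record("patterns", {
        "membership": out / "membership.tsv",
        "prototypes": out / "prototypes.tsv",
        "assignments": out / "assignments.tsv",
        "sizes": out / "pattern_sizes.json",
        "long": out / "prototypes_long.csv",
    }, {"n_patterns": patterns.n_patterns, "sizes": sizes})


def _gene_sets(cfg, out, state) -> dict[str, list[str]]:
    """Analyzed gene sets: DP memberships plus per-stage DE lists.

    Falls back to the upstream stage's files so enrich/modules can rerun
    alone on existing artifacts.
    """
    sets: dict[str, list[str]] = {}
    patterns = state.get("patterns")
    if patterns is not None and not patterns.assignments.empty:
        assigned = patterns.assignments.dropna(subset=["pattern"])
        for pid, block in assigned.groupby("pattern"):
            sets[str(pid)] = sorted(block.index)
    elif (out / "assignments.tsv").exists():
        assigned = pd.read_csv(out / "assignments.tsv", sep="\t",
                               index_col="gene").dropna(subset=["pattern"])
        for pid, block in assigned.groupby("pattern"):
            sets[str(pid)] = sorted(block.index)
    diff_results = state.get("diff")
    if diff_results is None:
        diff_results = {}
        for stage_name in cfg.stages:
            path = out / f"diff_{stage_name}.tsv"
            if path.exists():
                diff_results[stage_name] = pd.read_csv(path, sep="\t",
                                                       index_col="gene")
    for stage_name, result in diff_results.items():
        deg = select_deg(result, fc_threshold=cfg.fc_threshold)
        if deg["up"]:
            sets[f"{stage_name}_up"] = sorted(deg["up"])
        if deg["down"]:
            sets[f"{stage_name}_down"] = sorted(deg["down"])
    return sets


def _compute_enrichment(cfg, out, state) -> None:
    """Fill state with enrichment results (shared by enrich and modules)."""
    promoters_path = out / "promoters.fasta"
    if not promoters_path.exists():
        raise FileNotFoundError(f"promoter FASTA missing: {promoters_path}")
    matrix = _get_matrix(out, state)
    gmt = io.read_gmt(out / "terms.gmt")
    promoters = io.read_fasta(promoters_path)
    motifs = io.read_motif_table(out / "motifs.tsv")
    background = matrix.gene_ids
    hit_table = motif_hit_table(promoters, motifs)
    gene_sets = _gene_sets(cfg, out, state)
    go_results, motif_results = {}, {}
    for name, genes in gene_sets.items():
        go_results[name] = go_enrichment(genes, gmt, background)
        motif_results[name] = motif_enrichment(
            genes, promoters, motifs, background, hit_table=hit_table)
    state.update(hit_table=hit_table, gene_sets=gene_sets,
                 go_results=go_results, motif_results=motif_results)


def _stage_enrich(cfg, out, state, record):
    _compute_enrichment(cfg, out, state)
    go_results = state["go_results"]
    motif_results = state["motif_results"]
    gene_sets = state["gene_sets"]
    go_rows = [t.assign(gene_set=n) for n, t in go_results.items()]
    motif_rows = [t.assign(gene_set=n) for n, t in motif_results.items()]
    (pd.concat(go_rows) if go_rows else pd.DataFrame()).to_csv(
        out / "go_enrichment.csv", index=False)
    (pd.concat(motif_rows) if motif_rows else pd.DataFrame()).to_csv(
        out / "motif_enrichment.csv", index=False)
    log10_matrix(go_results).rename_axis("term").to_csv(
        out / "go_log10p.tsv", sep="\t")
    n_enriched = int(sum((t["enriched"]).sum() for t in go_results.values()))
    record("enrich", {
        "go": out / "go_enrichment.csv",
        "motif": out / "motif_enrichment.csv",
        "log10": out / "go_log10p.tsv",
    }, {"n_gene_sets": len(gene_sets), "n_enriched_go": n_enriched})


def _stage_modules(cfg, out, state, record):
    if "motif_results" not in state:
        _compute_enrichment(cfg, out, state)
    gmt = io.read_gmt(out / "terms.gmt")
    tf_map = io.read_tf_map(out / "tf_map.tsv")
    hit_table = state["hit_table"]
    paths = {}
    graphs = {}
    for name, genes in state["gene_sets"].items():
        mo = state["motif_results"][name]
        if not mo["enriched"].any():
            continue
        graph = build_module(genes, mo, tf_map, hit_table,
                             go_results=state["go_results"][name], gmt=gmt)
        files = export_cytoscape(graph, out / f"module_{name}")
        io.write_json(graph_to_json(graph), out / f"module_{name}.json")
        for kind, p in files.items():
            paths[f"{name}_{kind}"] = p
        paths[f"{name}_json"] = out / f"module_{name}.json"
        graphs[name] = graph
    state["modules"] = graphs
    record("modules", paths, {"n_modules": len(graphs)})


def _stage_qpcr(cfg, out, state, record):
    dataset = state.get("dataset")
    if dataset is None:
        return
    truth = dataset.truth
    # validate a few planted differential genes against their array folds
    stage0 = cfg.stages[0]
    genes = list(truth.de_genes.get(stage0, {}))[:3]
    if not genes:
        record("qpcr", {}, {"n_genes": 0})
        return
    ref = "REF"
    cells = [f"{cfg.genotypes[0]}:{stage0}", f"{cfg.genotypes[1]}:{stage0}"]
    expr = dataset.gene_means.loc[genes, cells].copy()
    expr.loc[ref] = 8.0  # flat reference transcript
    ct = generate_qpcr_table(expr, ref, seed=cfg.seed + 3, noise_sd=0.0)
    ct.to_csv(out / "qpcr_ct.csv", index=False)
    folds = ddct_table(ct, reference=ref, calibrator=cells[0])
    folds.to_csv(out / "qpcr_folds.csv", index=False)
    record("qpcr", {"ct": out / "qpcr_ct.csv", "folds": out / "qpcr_folds.csv"},
           {"n_genes": len(genes)})


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "detect": _stage_detect,
    "diff": _stage_diff,
    "patterns": _stage_patterns,
    "enrich": _stage_enrich,
    "modules": _stage_modules,
    "qpcr": _stage_qpcr,
}
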