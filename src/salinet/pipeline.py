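"""End-to-end orchestration: filter, classify, analyse, write results.

``run_pipeline`` executes the full stage sequence (filter -> salinity
classes -> diversity/ordination -> indicators -> per-class networks ->
assembly null models -> biomarkers) on one data set, writing each
stage's tables plus a manifest recording parameters, derived seeds and
output checksums.  Stage seeds are derived deterministically from the
master seed and the stage name, so stages are independently reproducible
from a single knob.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assembly, biomarkers, diversity, indicators, io, network, ordination
from .datatypes import (
    OtuTable,
    Phylogeny,
    SalinetError,
    SampleMetadata,
    TaxonomyTable,
    classify_salinity_series,
)

logger = logging.getLogger("salinet")

STAGES = ("filter", "diversity", "indicators", "network", "assembly", "biomarkers")


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) % (2**31)


@dataclass
class RunConfig:
    otu_table: str
    taxonomy: str
    metadata: str
    tree: str
    out_dir: str
    seed: int = 0
    orientation: str = "otus_as_rows"
    n_permutations: int = 999
    n_null: int = 199
    null_graphs: int = 1000
    rho_min: float = network.DEFAULT_RHO_MIN
    q_max: float = network.DEFAULT_Q_MAX
    min_prevalence: float = 0.25
    indval_min: float = indicators.DEFAULT_INDVAL_MIN
    indval_p_max: float = indicators.DEFAULT_P_MAX
    mrt_cv: int = 100
    rf_trees: int = 200
    rf_folds: int = 10
    rf_repeats: int = 2
    env_variables: list[str] = field(default_factory=lambda: ["salinity", "TP", "Chla", "WT"])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: RunConfig):
    table = io.parse_otu_table(config.otu_table, orientation=config.orientation)
    taxonomy = io.parse_taxonomy(config.taxonomy)
    metadata = io.parse_metadata(config.metadata)
    tree = io.parse_tree(config.tree)
    missing_meta = set(table.sample_ids) - set(metadata.sample_ids)
    if missing_meta:
        raise SalinetError(f"samples missing from metadata: {sorted(missing_meta)}")
    taxonomy.require_covers(table.otu_ids)
    metadata = SampleMetadata(metadata.data.loc[table.sample_ids])
    return table, taxonomy, metadata, tree


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    table, taxonomy, metadata, tree = _load_inputs(config)

    # --- filter ---------------------------------------------------------
    filtered = io.filter_otus(table, taxonomy)
    io.write_otu_table(filtered, out / "filtered_otu_table.tsv")
    groups = classify_salinity_series(metadata.data["salinity"])
    groups.to_frame().to_csv(out / "salinity_classes.tsv", sep="\t", index_label="sample_id")
    manifest["stages"]["filter"] = {
        "n_otus_in": table.n_otus,
        "n_otus_out": filtered.n_otus,
        "outputs": ["filtered_otu_table.tsv", "salinity_classes.tsv"],
    }

    # --- diversity / ordination ----------------------------------------
    seed = derive_seed(config.seed, "diversity")
    alpha = diversity.alpha_diversity(filtered)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
    bc = diversity.bray_curtis(filtered)
    pd.DataFrame(bc.data, index=bc.ids, columns=bc.ids).to_csv(
        out / "bray_curtis.tsv", sep="\t", index_label="sample_id"
    )
    nmds_res = diversity.nmds(bc, seed=seed, n_starts=20)
    nmds_res.coordinates.assign(stress=nmds_res.stress).to_csv(
        out / "nmds.tsv", sep="\t"
    )
    perm = diversity.permanova(bc, groups, n_perm=config.n_permutations, seed=seed)
    manifest["stages"]["diversity"] = {
        "seed": seed,
        "nmds_stress": nmds_res.stress,
        "permanova": dataclasses.asdict(perm),
        "outputs": ["alpha_diversity.tsv", "bray_curtis.tsv", "nmds.tsv"],
    }

    # --- indicators -----------------------------------------------------
    seed = derive_seed(config.seed, "indicators")
    ind = indicators.indval(
        filtered, groups, n_perm=config.n_permutations, seed=seed,
        indval_min=config.indval_min, p_max=config.indval_p_max,
    )
    ind.to_csv(out / "indicators.tsv", sep="\t")
    manifest["stages"]["indicators"] = {
        "seed": seed,
        "n_indicators": int(ind["is_indicator"].sum()),
        "outputs": ["indicators.tsv"],
    }

    # --- networks per salinity class ------------------------------------
    seed = derive_seed(config.seed, "network")
    net_stage: dict = {"seed": seed, "groups": {}, "outputs": []}
    for cls in sorted(groups.unique()):
        samples = groups.index[groups == cls].tolist()
        if len(samples) < 4:
            logger.warning("network stage: class %s has <4 samples, skipped", cls)
            continue
        sub = filtered.select_samples(samples)
        try:
            prev = network.prevalence_filter(sub, config.min_prevalence)
            edges = network.spearman_edges(prev, rho_min=config.rho_min, q_max=config.q_max)
            g = network.build_network(edges, taxonomy)
            if g.number_of_nodes() < 2:
                raise SalinetError("fewer than 2 connected nodes")
            topo = network.topology(g)
            nulls = network.er_null_ensemble(
                topo.n_nodes, topo.n_links, n_graphs=config.null_graphs,
                seed=seed, observed=topo,
            )
            fname = f"network_{cls}_edges.tsv"
            edges.to_csv(out / fname, sep="\t", index=False)
            net_stage["groups"][cls] = {
                "topology": dataclasses.asdict(topo),
                "null_means": nulls.means,
                "null_sds": nulls.sds,
                "z_scores": nulls.z_scores,
            }
            net_stage["outputs"].append(fname)
        except SalinetError as exc:
            logger.warning("network stage failed for class %s: %s", cls, exc)
            net_stage["groups"][cls] = {"error": str(exc)}
    manifest["stages"]["network"] = net_stage

    # --- assembly --------------------------------------------------------
    seed = derive_seed(config.seed, "assembly")
    try:
        pairs = assembly.assembly_pairs(filtered, tree, n_null=config.n_null, seed=seed)
        pairs.to_csv(out / "assembly_pairs.tsv", sep="\t", index=False)
        frac = assembly.process_fractions(pairs, groups)
        summary = {
            "fractions": frac.fractions.to_dict(orient="index"),
            "bnti_summary": frac.bnti_summary.to_dict(orient="index"),
            "kruskal_h": frac.kruskal_h,
            "kruskal_p": frac.kruskal_p,
            "n_undefined": frac.n_undefined,
        }
        (out / "assembly_summary.json").write_text(json.dumps(summary, indent=2))
        manifest["stages"]["assembly"] = {
            "seed": seed,
            "n_null": config.n_null,
            "outputs": ["assembly_pairs.tsv", "assembly_summary.json"],
        }
    except SalinetError as exc:
        logger.warning("assembly stage failed: %s", exc)
        manifest["stages"]["assembly"] = {"error": str(exc)}

    # --- biomarkers (optional: may fail on tiny data) --------------------
    seed = derive_seed(config.seed, "biomarkers")
    try:
        feats = biomarkers.aggregate_to_rank(filtered, taxonomy, rank="order")
        rf = biomarkers.rfcv_biomarkers(
            feats, metadata.data["salinity"], ntree=config.rf_trees,
            folds=min(config.rf_folds, filtered.n_samples),
            repeats=config.rf_repeats, seed=seed,
        )
        rf.importances.to_csv(out / "rf_importance.tsv", sep="\t", header=["importance"])
        rf.cv_errors.to_csv(out / "rf_cv_errors.tsv", sep="\t", index=False)
        manifest["stages"]["biomarkers"] = {
            "seed": seed,
            "selected_markers": rf.selected_markers,
            "accuracy_pct": rf.accuracy_pct,
            "wilcoxon_p": rf.wilcoxon_p,
            "outputs": ["rf_importance.tsv", "rf_cv_errors.tsv"],
        }
    except (SalinetError, ValueError) as exc:
        logger.warning("biomarker stage failed (non-fatal): %s", exc)
        manifest["stages"]["biomarkers"] = {"error": str(exc)}

    checksums = {}
    for stage in manifest["stages"].values():
        for fname in stage.get("outputs", []):
            checksums[fname] = _sha256(out / fname)
    manifest["checksums"] = checksums
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
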