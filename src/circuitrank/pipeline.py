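"""End-to-end orchestration: simulate/load -> activities -> relevance ->
selection -> stability, with a manifest recording seeds, digests and timings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .activity import ExpressionMatrix, compute_activities, normalize_expression
from .graphio import PathwayCollection, read_gene_list, read_pathways, write_gene_list, write_pathways
from .relevance import RelevanceConfig, compute_relevance
from .selection import circuits_per_target, select_all, selections_to_frame, summary_to_frame
from .simulate import SimulationConfig, simulate_dataset
from .stability import run_stability_harness

logger = logging.getLogger(__name__)

STAGES = ("simulate", "normalize", "relevance", "selection", "stability")


def stage_seed(global_seed: int, stage: str) -> int:
    """Counter-based per-stage seed derivation from the single global seed."""
    k = STAGES.index(stage)
    return int(np.random.SeedSequence(entropy=global_seed, spawn_key=(k,)).generate_state(1)[0])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Execute the full pipeline; returns the manifest (also written to disk).

    The config either names input files (``inputs: {expression, pathways,
    kdt_list}``) or requests simulation (``simulate: {...}``). All stage
    seeds derive deterministically from the single top-level ``seed``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    global_seed = int(config.get("seed", 0))
    manifest: dict = {
        "version": __version__,
        "config": config,
        "seed": global_seed,
        "stage_seeds": {s: stage_seed(global_seed, s) for s in STAGES},
        "timings_s": {},
        "outputs": {},
    }
    timings = manifest["timings_s"]

    def done(stage: str, t0: float) -> None:
        timings[stage] = round(time.perf_counter() - t0, 4)
        logger.info("stage %s finished in %.2fs", stage, timings[stage])

    # --- inputs -----------------------------------------------------------
    t0 = time.perf_counter()
    truth = None
    if "inputs" in config:
        inputs = config["inputs"]
        for key in ("expression", "pathways", "kdt_list"):
            if key not in inputs:
                raise ValueError(f"config inputs missing {key!r}")
            if not Path(inputs[key]).exists():
                raise FileNotFoundError(f"input missing: {key} file {inputs[key]!r}")
        raw_expr = ExpressionMatrix.from_tsv(inputs["expression"])
        collection = read_pathways(inputs["pathways"])
        kdt_genes = read_gene_list(inputs["kdt_list"])
    else:
        sim_kwargs = dict(config.get("simulate", {}))
        sim_kwargs.setdefault("seed", stage_seed(global_seed, "simulate"))
        if "chain_length_range" in sim_kwargs:
            sim_kwargs["chain_length_range"] = tuple(sim_kwargs["chain_length_range"])
        sim_config = SimulationConfig(**sim_kwargs)
        collection, truth, raw_expr = simulate_dataset(sim_config)
        kdt_genes = sim_config.kdt_genes
        raw_expr.to_tsv(outdir / "expression.tsv")
        write_pathways(collection, outdir / "pathways.json")
        write_gene_list(kdt_genes, outdir / "kdt_list.txt")
        truth.to_json(outdir / "truth.json")
    done("simulate", t0)

    # --- activities -------------------------------------------------------
    t0 = time.perf_counter()
    norm_cfg = config.get("normalize", {})
    norm = normalize_expression(raw_expr, upper_quantile=norm_cfg.get("upper_quantile", 0.99))
    activities = compute_activities(
        collection, norm,
        aggregator=norm_cfg.get("aggregator", "mean"),
        missing=norm_cfg.get("missing", "error"),
    )
    activities.to_tsv(outdir / "activities.tsv")
    done("normalize", t0)

    # --- relevance --------------------------------------------------------
    t0 = time.perf_counter()
    rel_cfg = dict(config.get("relevance", {}))
    rel_cfg.setdefault("seed", stage_seed(global_seed, "relevance"))
    rel_config = RelevanceConfig(kdt_genes=kdt_genes, **rel_cfg)
    result, model = compute_relevance(norm, activities, rel_config)
    result.relevance_frame().to_csv(
        outdir / "relevance.tsv", sep="\t", index_label="gene", float_format="%.6g"
    )
    with open(outdir / "r2.tsv", "w") as fh:
        fh.write("circuit_id\tr2\n")
        for cid, r2 in zip(result.circuit_ids, result.r2):
            fh.write(f"{cid}\t{r2:.6g}\n")
    result.global_frame().to_csv(
        outdir / "global_relevance.tsv", sep="\t", index=False, float_format="%.6g"
    )
    done("relevance", t0)

    # --- selection --------------------------------------------------------
    t0 = time.perf_counter()
    gamma = config.get("selection", {}).get("gamma", 1.0)
    selections = select_all(
        result.gene_ids, result.circuit_ids, result.relevance, result.r2, gamma=gamma
    )
    selections_to_frame(selections).to_csv(
        outdir / "selection.tsv", sep="\t", index=False, float_format="%.6g"
    )
    summary = circuits_per_target(selections, kdt_genes, collection.circuit_pathway_map())
    summary_to_frame(summary).to_csv(outdir / "target_summary.tsv", sep="\t", index=False)
    done("selection", t0)

    # --- stability --------------------------------------------------------
    stab_cfg = dict(config.get("stability", {}))
    if stab_cfg.pop("enabled", False):
        t0 = time.perf_counter()
        Z, report = run_stability_harness(
            collection,
            raw_expr,
            rel_config,
            M=stab_cfg.get("M", 30),
            subsample_fraction=stab_cfg.get("subsample_fraction", 0.8),
            seed=stage_seed(global_seed, "stability"),
            gamma=gamma,
            upper_quantile=norm_cfg.get("upper_quantile", 0.99),
            bootstrap_reps=stab_cfg.get("bootstrap_reps", 1000),
            null_draws=stab_cfg.get("null_draws", 500),
        )
        Z.to_tsv(outdir / "selection_matrix.tsv")
        report.to_json(outdir / "stability.json")
        done("stability", t0)

    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
        fh.write("\n")
    return manifest
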