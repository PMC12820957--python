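"""Configuration-driven orchestration of the full consensus analysis.

Per target the pipeline runs: relative ranking -> Borda/aggregated rank and
ECR -> KDE intersection threshold and classification metrics per scoring
function -> consensus interaction fingerprints, Tanimoto similarity and
clustering -> correlation of scores and consensus values to pIC50 (when
activities are available).  Artifacts are plain CSV/JSON under one output
directory per target, plus a run manifest with a config hash and the seed
so identical runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import correlate as _correlate
from . import fingerprints as _fp
from . import ranking as _ranking
from .io import (
    ActivityTable,
    MechClass,
    ScoreTable,
    read_activity_table,
    read_annotations,
    read_function_specs,
    read_plip_records,
    read_score_table,
)
from .synthetic import GeneratorConfig, generate_study, write_study

logger = logging.getLogger("consdock")

__all__ = ["PipelineConfig", "run_pipeline"]

# which mechanistic class counts as "positive" per target
_POSITIVE = {"CI": MechClass.CI_inhibitor, "CIII": MechClass.CIII_inhibitor}


@dataclass
class PipelineConfig:
    """Everything a run needs: either a synthetic generator config or
    paths to real input files, plus the consensus/fingerprint options."""

    outdir: str
    seed: int = 0
    synthetic: GeneratorConfig | None = None
    score_tables: dict[str, str] = field(default_factory=dict)  # target -> csv
    functions_path: str | None = None
    annotations_path: str | None = None
    interactions: dict[str, dict[str, str]] = field(default_factory=dict)
    # target -> program -> path
    activities_path: str | None = None
    activity_target: str = "CIII"
    sigma: float = 10.0
    prefactor: bool = True
    missing_policy: str = "worst_rank"
    linkage: str = "average"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            cfg.synthetic = GeneratorConfig(**syn)
        return cfg

    def config_hash(self) -> str:
        d = asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _round_floats(obj: Any, ndigits: int = 6) -> Any:
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _write_json(path: Path, obj: Any) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute the full analysis; returns the run manifest (also written
    to ``<outdir>/manifest.json``).  Input files are never mutated."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "artifacts": [],
        "warnings": [],
    }

    # ---- gather inputs -----------------------------------------------
    if cfg.synthetic is not None:
        syn = GeneratorConfig(**{**asdict(cfg.synthetic), "seed": cfg.seed})
        bundle = generate_study(syn)
        inputs_dir = out / "inputs"
        write_study(bundle, inputs_dir)
        specs = bundle.specs
        tables = bundle.score_tables
        annotations = bundle.annotations
        interactions = bundle.interactions
        activities: ActivityTable | None = bundle.activities
        activity_target = syn.activity_target
    else:
        if cfg.functions_path is None or not cfg.score_tables:
            raise FileNotFoundError(
                "non-synthetic run requires functions_path and score_tables"
            )
        specs = read_function_specs(cfg.functions_path)
        tables = {
            t: read_score_table(p, specs, target_id=t)
            for t, p in cfg.score_tables.items()
        }
        annotations = (
            read_annotations(cfg.annotations_path) if cfg.annotations_path else []
        )
        interactions = {}
        for target, per_prog in cfg.interactions.items():
            for program, path in per_prog.items():
                interactions[(target, program)] = read_plip_records(
                    path, program=program
                )
        activities = (
            read_activity_table(cfg.activities_path) if cfg.activities_path else None
        )
        activity_target = cfg.activity_target

    ann_map = {a.ligand_id: a.mech_class for a in annotations}

    # ---- per-target stages -------------------------------------------
    for target, table in tables.items():
        tdir = out / target
        tdir.mkdir(exist_ok=True)
        logger.info("target %s: %d ligands, %d functions",
                    target, len(table.ligand_ids), len(table.function_names))

        ranks = _ranking.relative_ranks(table, specs, cfg.missing_policy)  # type: ignore[arg-type]
        cons = _ranking.consensus(ranks, sigma=cfg.sigma, prefactor=cfg.prefactor)
        p = tdir / "ranks.csv"
        ranks.ranks.rename_axis("ligand_id").to_csv(p)
        manifest["artifacts"].append(str(p.relative_to(out)))
        p = tdir / "consensus.csv"
        pd.DataFrame(
            {"borda": cons.borda, "aggregated_rank": cons.aggregated_rank,
             "ecr": cons.ecr}
        ).rename_axis("ligand_id").to_csv(p)
        manifest["artifacts"].append(str(p.relative_to(out)))

        # KDE thresholds + metrics per function (needs annotations)
        thresholds: dict[str, Any] = {}
        metrics: dict[str, Any] = {}
        pos_class = _POSITIVE.get(target)
        if ann_map and pos_class is not None:
            truth = {
                lig: "positive" if ann_map.get(lig) is pos_class else "negative"
                for lig in table.ligand_ids
                if lig in ann_map
            }
            for fn in table.function_names:
                col = table.scores[fn]
                pos_vals = [col[l] for l in truth if truth[l] == "positive"
                            and not np.isnan(col[l])]
                neg_vals = [col[l] for l in truth if truth[l] == "negative"
                            and not np.isnan(col[l])]
                try:
                    model = _classify.intersection_threshold(
                        pos_vals, neg_vals, function_name=fn
                    )
                except ValueError as exc:
                    thresholds[fn] = {"error": str(exc)}
                    manifest["warnings"].append(f"{target}/{fn}: {exc}")
                    continue
                thresholds[fn] = json.loads(model.to_json())
                pred = _classify.classify_by_threshold(
                    {l: col[l] for l in truth}, model
                )
                m = _classify.classification_metrics(pred, truth)
                metrics[fn] = json.loads(m.to_json())
        p = tdir / "thresholds.json"
        _write_json(p, _round_floats(thresholds))
        manifest["artifacts"].append(str(p.relative_to(out)))
        p = tdir / "metrics.json"
        _write_json(p, _round_floats(metrics))
        manifest["artifacts"].append(str(p.relative_to(out)))

        # fingerprints (needs interaction records from two programs)
        progs = sorted({pr for (t, pr) in interactions if t == target})
        if len(progs) >= 2:
            recs_a = interactions[(target, progs[0])]
            recs_b = interactions[(target, progs[1])]
            sets = _fp.merge_consensus_interactions(recs_a, recs_b)
            fpm = _fp.build_fingerprint_matrix(sets)
            sim = _fp.tanimoto_matrix(fpm)
            p = tdir / "fingerprints.csv"
            fpm.matrix.to_csv(p)
            manifest["artifacts"].append(str(p.relative_to(out)))
            p = tdir / "similarity.csv"
            sim.to_frame().round(6).rename_axis("ligand_id").to_csv(p)
            manifest["artifacts"].append(str(p.relative_to(out)))
            if len(sim.ligand_ids) >= 2:
                dend = _fp.cluster_fingerprints(sim, linkage=cfg.linkage)  # type: ignore[arg-type]
                p = tdir / "dendrogram.json"
                p.write_text(dend.to_json() + "\n")
                manifest["artifacts"].append(str(p.relative_to(out)))

        # activity correlation on the designated target
        if activities is not None and target == activity_target and len(activities) >= 3:
            correlations: dict[str, Any] = {}
            vectors: dict[str, dict[str, float]] = {
                fn: table.scores[fn].to_dict() for fn in table.function_names
            }
            vectors["ECR"] = cons.ecr.to_dict()
            vectors["aggregated_rank"] = cons.aggregated_rank.to_dict()
            for name, vec in vectors.items():
                try:
                    rho, r = _correlate.rank_correlation(vec, activities.pic50)
                    correlations[name] = {
                        "n": len(set(vec) & set(activities.pic50)),
                        "spearman_rho": rho,
                        "pearson_r": r,
                    }
                except ValueError as exc:
                    correlations[name] = {"error": str(exc)}
            p = tdir / "correlations.json"
            _write_json(p, _round_floats(correlations))
            manifest["artifacts"].append(str(p.relative_to(out)))

    _write_json(out / "manifest.json", manifest)
    return manifest
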