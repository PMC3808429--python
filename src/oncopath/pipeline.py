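"""End-to-end orchestration: build → centralities → train → compare →
score → extract → evaluate, with a reproducibility manifest.

A run is driven by a :class:`RunConfig` (YAML-loadable) whose numeric knobs
default to the method's published settings: 1000 normal datasets, 10
shuffles each, 20 bags, 10 folds, the 41-value K ladder, OP > 0.7 for
enrichment, and a 0.005 significance threshold.  Desk-scale runs override
the dataset counts and ladder.

Seed scoping: the master seed drives training-stage randomness (negative
sampling, shuffling, bootstrap, folds) through named substreams; network
construction from input files is seed-free, so reruns with a different
master seed reproduce the network stage bit-for-bit and differ only from
the training stage onward.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import centrality, network, scoring, subnetwork, training
from .evaluation import evaluate_subnetworks, read_linear_pathways
from .pathfinding import DEFAULT_K_LADDER

logger = logging.getLogger("oncopath")

STAGES = (
    "build",
    "centralities",
    "train",
    "compare",
    "score",
    "extract",
    "evaluate",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """All inputs and knobs of a full run; defaults are the published ones."""

    physical: str | None = None
    regulatory: str | None = None
    metabolic: str | None = None
    reactions: str | None = None
    positives: str | None = None
    pathways: str | None = None  # reference linear pathways; endpoints define pairs
    outdir: str = "oncopath_run"

    n_datasets: int = 1000
    n_shuffles: int = 10
    n_bags: int = 20
    k_folds: int = 10
    k_ladder: list[int] = field(default_factory=lambda: list(DEFAULT_K_LADDER))
    enrichment_threshold: float = 0.7
    p_threshold: float = 0.005
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _hash_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute every stage and return (and write) the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": cfg.seed,
        "config": {k: v for k, v in vars(cfg).items()},
        "inputs": {},
        "stages": {},
    }
    for key in ("physical", "regulatory", "metabolic", "reactions", "positives", "pathways"):
        path = getattr(cfg, key)
        if path:
            manifest["inputs"][key] = {"path": str(path), "sha256": _hash_file(path)}

    def stage(name):
        def deco(fn):
            t0 = time.time()
            manifest["stages"][name] = {}
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001
                del manifest["stages"][name]
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name]["seconds"] = round(time.time() - t0, 2)
            return result

        return deco

    @stage("build")
    def net():
        parts = []
        if cfg.physical:
            phys = network.read_edge_list(cfg.physical, "physical")
            pairs = {tuple(sorted(e)) for e in phys.simple_edges()}
            parts.append(network.direct_physical_edges(sorted(pairs)))
        if cfg.regulatory:
            parts.append(network.read_edge_list(cfg.regulatory, "regulatory"))
        if cfg.metabolic:
            parts.append(network.read_edge_list(cfg.metabolic, "metabolic"))
        if cfg.reactions:
            rt = network.ReactionTable.read_tsv(cfg.reactions)
            parts.append(network.derive_metabolic_interactions(rt))
        if not parts:
            raise ValueError("no network inputs configured")
        return network.integrate(parts)

    manifest["stages"]["build"]["n_genes"] = len(net)
    manifest["stages"]["build"]["n_typed_edges"] = net.n_edges()
    net.write_graphml(outdir / "network.graphml")

    @stage("centralities")
    def cent():
        table = centrality.centrality_table(net)
        centrality.write_centralities(table, outdir / "centralities.tsv")
        return table

    @stage("train")
    def trained():
        pos_net = network.read_edge_list(cfg.positives, "regulatory")
        positives = sorted(pos_net.simple_edges() & net.simple_edges())
        if not positives:
            raise ValueError("no positive edges map onto the network")
        datasets = training.sample_normal_datasets(
            net, cent, positives, cfg.n_datasets,
            seed=training.derive_seed(cfg.seed, "negatives"),
        )
        normal_models, normal_reports, shuffled_reports = [], [], []
        for i, ds in enumerate(datasets):
            normal_models.append(
                training.train_bagged_trees(
                    ds, cfg.n_bags, seed=training.derive_seed(cfg.seed, f"bag/{i}")
                )
            )
            normal_reports.append(
                training.cross_validate(
                    ds, cfg.k_folds, cfg.n_bags,
                    seed=training.derive_seed(cfg.seed, f"cv/{i}"),
                )
            )
            for j, sh in enumerate(
                training.shuffle_labels(
                    ds, cfg.n_shuffles, seed=training.derive_seed(cfg.seed, f"shuffle/{i}")
                )
            ):
                shuffled_reports.append(
                    training.cross_validate(
                        sh, cfg.k_folds, cfg.n_bags,
                        seed=training.derive_seed(cfg.seed, f"cv/{i}/{j}"),
                    )
                )
        return positives, normal_models, normal_reports, shuffled_reports

    positives, normal_models, normal_reports, shuffled_reports = trained

    @stage("compare")
    def comparison():
        return training.compare_normal_vs_shuffled(
            normal_reports, shuffled_reports, alpha=cfg.p_threshold
        )

    manifest["stages"]["compare"].update(
        medians_normal=comparison.medians_normal,
        medians_shuffled=comparison.medians_shuffled,
        p_values=comparison.p_values,
        significant=comparison.significant,
    )

    @stage("score")
    def scored():
        ens = scoring.combine_models(normal_models)
        sn = scoring.assign_scores(net, cent, ens)
        enr = scoring.enrichment_test(sn, set(positives), cfg.enrichment_threshold)
        manifest["stages"]["score"]["enrichment"] = vars(enr)
        net.write_graphml(outdir / "scored_network.graphml", op=sn.op)
        return sn

    @stage("extract")
    def extracted():
        if not cfg.pathways:
            return [], []
        olps = read_linear_pathways(cfg.pathways)
        subs = []
        kept = []
        for olp in olps:
            res = subnetwork.extract_signaling_subnetwork(
                scored, olp.genes[0], olp.genes[-1], cfg.k_ladder
            )
            if res.candidate is not None:
                subs.append(res.candidate)
                kept.append(olp)
            else:
                logger.warning("pair %s -> %s: %s", olp.genes[0], olp.genes[-1], res.status)
        return subs, kept

    subs, kept_olps = extracted
    manifest["stages"]["extract"]["n_subnetworks"] = len(subs)

    @stage("evaluate")
    def report():
        if not subs:
            return None
        rep = evaluate_subnetworks(subs, kept_olps)
        manifest["stages"]["evaluate"].update(rep.as_dict())
        return rep

    manifest["completed_stages"] = [s for s in STAGES if s in manifest["stages"]]
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return str(obj)
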