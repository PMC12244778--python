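"""End-to-end analysis pipeline and report bundle.

Stage order: load -> descriptives -> prevalence filter -> covariate screen ->
cluster extraction -> network estimation (without and with covariate nodes)
-> centrality/bridge/predictability -> bootstrap stability -> subgroup
network comparisons.  Every stage logs its input/output shapes; any failure
aborts with a stage-labeled error.  All randomness derives from the single
seed in the configuration, so a bundle is regenerable bit-identically from
its manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    DatasetSchema,
    SymptomDataset,
    covariate_screen,
    cronbach_alpha,
    descriptives,
    filter_by_prevalence,
    load_dataset,
)
from .comparison import NCTResult, network_comparison_test, split_by_covariate
from .errors import SympnetError, ValidationError
from .factors import extract_clusters
from .generate import sample_dataset, study_like_config
from .ggm import estimate_network
from .metrics import full_centrality
from .stability import bootstrap_edges, case_dropping, cs_coefficient

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "input": {"synthetic": "study_like", "seed": 0},
    "prevalence_threshold": 0.20,
    "screen_p_threshold": 0.05,
    "min_loading": 0.5,
    "gamma": 0.5,
    "n_lambda": 100,
    "lambda_min_ratio": 0.01,
    "covariates": None,  # None -> use screen-flagged covariates
    "stability": {"enabled": True, "B": 250, "drop_B": 100},
    "comparisons": [],  # e.g. ["female", "smoking"]
    "n_perm": 1000,
    "seed": 0,
}

KNOWN_KEYS = set(DEFAULT_CONFIG)


class StageError(SympnetError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ReportBundle:
    """All artifacts of one pipeline run."""

    config: dict
    dataset: SymptomDataset
    descriptives: pd.DataFrame
    total_score: tuple
    alpha: float
    dropped_symptoms: list
    screen: object
    clusters: object
    network: object
    network_adjusted: object | None
    centrality: pd.DataFrame
    centrality_adjusted: pd.DataFrame | None
    stability: dict
    comparisons: dict[str, NCTResult]
    manifest: dict = field(default_factory=dict)


def _validate_config(config: dict) -> dict:
    unknown = set(config) - KNOWN_KEYS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    merged = {**DEFAULT_CONFIG, **config}
    merged["stability"] = {**DEFAULT_CONFIG["stability"], **(merged["stability"] or {})}
    return merged


def _obtain_dataset(cfg: dict) -> SymptomDataset:
    src = cfg["input"]
    if "synthetic" in src:
        if src["synthetic"] != "study_like":
            raise ValidationError(f"unknown synthetic preset {src['synthetic']!r}")
        gen = study_like_config(seed=int(src.get("seed", cfg["seed"])))
        return sample_dataset(gen)
    if "path" not in src:
        raise ValidationError("config input needs either 'synthetic' or 'path'")
    schema = DatasetSchema(
        symptoms=src["schema"]["symptoms"],
        covariates=src["schema"].get("covariates", ()),
    )
    return load_dataset(src["path"], schema)


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> ReportBundle:
    """Run every stage from a single configuration (dict or JSON path)."""
    if isinstance(config, (str, Path)):
        config = json.loads(Path(config).read_text())
    cfg = _validate_config(config)
    seed = int(cfg["seed"])

    def stage(name, fn):
        try:
            out = fn()
        except SympnetError as exc:
            raise StageError(name, exc) from exc
        log.info("stage %s done", name)
        return out

    dataset = stage("load", lambda: _obtain_dataset(cfg))
    log.info("dataset: n=%d p=%d", dataset.n, dataset.p)

    desc, total = stage("describe", lambda: descriptives(dataset))
    alpha = stage("describe", lambda: cronbach_alpha(dataset.severities))
    filtered, dropped = stage(
        "filter", lambda: filter_by_prevalence(dataset, cfg["prevalence_threshold"])
    )

    screen = None
    if dataset.covariates.shape[1] >= 2:
        screen = stage(
            "screen",
            lambda: covariate_screen(dataset, p_threshold=cfg["screen_p_threshold"]),
        )
    covariates = cfg["covariates"]
    if covariates is None:
        covariates = screen.flagged_covariates if screen is not None else []

    clusters = stage(
        "cluster", lambda: extract_clusters(filtered, min_loading=cfg["min_loading"])
    )
    cluster_labels = {s: clusters.assignments.get(s) for s in filtered.symptom_names}
    for s in clusters.unassigned:
        cluster_labels[s] = f"unassigned:{s}"  # own singleton module

    est = {
        "gamma": cfg["gamma"],
        "n_lambda": cfg["n_lambda"],
        "lambda_min_ratio": cfg["lambda_min_ratio"],
    }
    network = stage(
        "network",
        lambda: estimate_network(filtered, cluster_labels=cluster_labels, **est),
    )
    network_adj = None
    if covariates:
        network_adj = stage(
            "network_adjusted",
            lambda: estimate_network(
                filtered, covariates=covariates, cluster_labels=cluster_labels, **est
            ),
        )

    centrality = stage("metrics", lambda: full_centrality(filtered, network))
    centrality_adj = (
        stage("metrics", lambda: full_centrality(filtered, network_adj))
        if network_adj is not None
        else None
    )

    stability: dict = {}
    stab_cfg = cfg["stability"]
    if stab_cfg.get("enabled", True):
        def run_stability():
            boot = bootstrap_edges(
                filtered, B=int(stab_cfg["B"]), seed=seed, estimation_settings=est
            )
            curves = case_dropping(
                filtered,
                metrics=("strength", "bridge_strength"),
                B=int(stab_cfg["drop_B"]),
                seed=seed + 1,
                estimation_settings=est,
                cluster_labels=cluster_labels,
            )
            return {
                "edge_ci": boot.edge_ci(),
                "cs": {
                    m: cs_coefficient(curves, metric=m)
                    for m in ("strength", "bridge_strength")
                },
                "curves": curves,
            }

        stability = stage("stability", run_stability)

    comparisons = {}
    for cov in cfg["comparisons"]:
        def run_cmp(cov=cov):
            ga, gb = split_by_covariate(filtered, cov)
            return network_comparison_test(
                ga, gb, n_perm=int(cfg["n_perm"]), seed=seed, estimation_settings=est
            )

        comparisons[cov] = stage(f"compare:{cov}", run_cmp)

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n": dataset.n,
        "p": dataset.p,
        "n_filtered": filtered.p,
    }
    bundle = ReportBundle(
        config=cfg,
        dataset=dataset,
        descriptives=desc,
        total_score=total,
        alpha=alpha,
        dropped_symptoms=dropped,
        screen=screen,
        clusters=clusters,
        network=network,
        network_adjusted=network_adj,
        centrality=centrality,
        centrality_adjusted=centrality_adj,
        stability=stability,
        comparisons=comparisons,
        manifest=manifest,
    )
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def write_bundle(bundle: ReportBundle, outdir: str | Path) -> None:
    """Write the bundle as CSV/JSON/GraphML files under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.descriptives.to_csv(out / "descriptives.csv", index=False)
    if bundle.screen is not None:
        bundle.screen.terms.to_csv(out / "covariate_screen.csv", index=False)
    bundle.clusters.to_table().to_csv(out / "clusters.csv")
    bundle.network.edge_list().to_csv(out / "network_edges.csv", index=False)
    bundle.network.write_graphml(out / "network.graphml")
    bundle.centrality.to_csv(out / "centrality.csv")
    if bundle.network_adjusted is not None:
        bundle.network_adjusted.edge_list().to_csv(
            out / "network_adjusted_edges.csv", index=False
        )
        bundle.network_adjusted.write_graphml(out / "network_adjusted.graphml")
        bundle.centrality_adjusted.to_csv(out / "centrality_adjusted.csv")
    if bundle.stability:
        bundle.stability["edge_ci"].to_csv(out / "edge_ci.csv", index=False)
        (out / "stability.json").write_text(json.dumps(bundle.stability["cs"], indent=2))
    for cov, res in bundle.comparisons.items():
        res.edge_table.to_csv(out / f"nct_{cov}_edges.csv", index=False)
        (out / f"nct_{cov}.json").write_text(
            json.dumps(
                {
                    "m_stat": res.m_stat,
                    "p_m": res.p_m,
                    "s_stat": res.s_stat,
                    "p_s": res.p_s,
                    "global_strength_a": res.global_strength_a,
                    "global_strength_b": res.global_strength_b,
                    "n_perm": res.n_perm,
                    "seed": res.seed,
                },
                indent=2,
            )
        )
    summary = {
        "total_score_mean": bundle.total_score[0],
        "total_score_sd": bundle.total_score[1],
        "cronbach_alpha": bundle.alpha,
        "dropped_symptoms": bundle.dropped_symptoms,
        "n_factors": bundle.clusters.n_factors,
        "kmo": bundle.clusters.kmo,
        "bartlett_chi2": bundle.clusters.bartlett_chi2,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    (out / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=2, default=str)
    )
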