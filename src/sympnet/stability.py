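"""Bootstrap accuracy and stability of the estimated network.

Three classical procedures: (1) nonparametric row-resampling bootstrap of
edge weights with percentile confidence intervals; (2) case-dropping
bootstrap of centrality indices summarized by the correlation-stability (CS)
coefficient — the largest drop proportion at which the correlation between
subsample and full-sample centralities stays at or above 0.7 with 95%
confidence (0.25 is the conventional minimum, above 0.5 is considered ideal);
(3) bootstrapped difference tests for pairs of edges or pairs of nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .cohort import SymptomDataset
from .ggm import SymptomNetwork, estimate_network
from .metrics import bridge_strength, centrality_table

log = logging.getLogger(__name__)

DEFAULT_DROP_PROPS = tuple(np.round(np.arange(0.05, 0.80, 0.05), 2))


def _estimate(dataset: SymptomDataset, settings: dict) -> SymptomNetwork:
    return estimate_network(dataset, **settings)


def _metric_vector(
    network: SymptomNetwork, metric: str, cluster_labels: dict | None
) -> np.ndarray:
    if metric == "strength":
        return centrality_table(network)["strength"].to_numpy()
    if metric == "bridge_strength":
        return bridge_strength(network, cluster_labels).to_numpy()
    if metric in {"closeness", "betweenness"}:
        return centrality_table(network)[metric].to_numpy()
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class EdgeBootstrap:
    """Row-resampling bootstrap of the edge-weight matrix."""

    node_names: list[str]
    sample_weights: np.ndarray  # observed p x p weights
    boot_weights: np.ndarray  # B x p x p replicate weights
    seed: int

    @property
    def n_boot(self) -> int:
        return self.boot_weights.shape[0]

    def edge_ci(self, level: float = 0.95) -> pd.DataFrame:
        """Percentile CI per upper-triangle edge, plus the observed weight."""
        lo, hi = 50 * (1 - level), 50 * (1 + level)
        p = len(self.node_names)
        rows = []
        for i in range(p):
            for j in range(i + 1, p):
                draws = self.boot_weights[:, i, j]
                rows.append(
                    {
                        "node_a": self.node_names[i],
                        "node_b": self.node_names[j],
                        "sample_edge": self.sample_weights[i, j],
                        "boot_mean": draws.mean(),
                        "ci_lower": np.percentile(draws, lo),
                        "ci_upper": np.percentile(draws, hi),
                    }
                )
        return pd.DataFrame(rows)


def bootstrap_edges(
    dataset: SymptomDataset,
    B: int = 1000,
    seed: int = 0,
    estimation_settings: dict | None = None,
    n_jobs: int = 1,
) -> EdgeBootstrap:
    """Nonparametric bootstrap: resample rows with replacement, re-estimate.

    Replicate b draws its indices from an independent child of ``seed``, so
    results are identical for any number of workers.
    """
    if B < 50:
        log.warning("B=%d bootstrap replicates is low; intervals will be noisy", B)
    settings = dict(estimation_settings or {})
    network = _estimate(dataset, settings)
    n = dataset.n
    children = np.random.SeedSequence(seed).spawn(B)

    def one(ss):
        rng = np.random.default_rng(ss)
        idx = rng.integers(0, n, size=n)
        return _estimate(dataset.subset_rows(idx), settings).weights

    mats = Parallel(n_jobs=n_jobs)(delayed(one)(ss) for ss in children)
    return EdgeBootstrap(
        node_names=list(network.node_names),
        sample_weights=network.weights,
        boot_weights=np.stack(mats),
        seed=seed,
    )


@dataclass
class StabilityCurves:
    """Case-dropping correlations per metric and drop proportion."""

    correlations: dict[str, pd.DataFrame]  # metric -> (len(props) x B) frame, index = props
    full_values: dict[str, np.ndarray]
    skipped: list[float] = field(default_factory=list)
    seed: int = 0


def case_dropping(
    dataset: SymptomDataset,
    metrics: Sequence[str] = ("strength",),
    drop_props: Sequence[float] = DEFAULT_DROP_PROPS,
    B: int = 1000,
    seed: int = 0,
    estimation_settings: dict | None = None,
    cluster_labels: dict | None = None,
    n_jobs: int = 1,
) -> StabilityCurves:
    """Case-dropping bootstrap: subsample rows without replacement, re-estimate.

    For each drop proportion q, B subsamples of size round(n(1-q)) are drawn;
    the recorded value is the Pearson correlation between the subsample and
    full-sample metric vectors.  Proportions leaving fewer than p+1 rows are
    skipped and logged.
    """
    settings = dict(estimation_settings or {})
    full_net = _estimate(dataset, settings)
    full = {m: _metric_vector(full_net, m, cluster_labels) for m in metrics}
    n, p = dataset.n, full_net.p

    usable, skipped = [], []
    for q in drop_props:
        if round(n * (1 - q)) < p + 1:
            skipped.append(q)
            log.info("drop proportion %.2f leaves < p+1 rows; skipped", q)
        else:
            usable.append(q)

    children = np.random.SeedSequence(seed).spawn(len(usable) * B)

    def one(q, ss):
        rng = np.random.default_rng(ss)
        m = round(n * (1 - q))
        idx = rng.choice(n, size=m, replace=False)
        net = _estimate(dataset.subset_rows(idx), settings)
        out = {}
        for metric in metrics:
            v = _metric_vector(net, metric, cluster_labels)
            f = full[metric]
            if v.std() == 0 or f.std() == 0:
                out[metric] = np.nan
            else:
                out[metric] = float(np.corrcoef(v, f)[0, 1])
        return out

    tasks = [(q, children[t * B + b]) for t, q in enumerate(usable) for b in range(B)]
    results = Parallel(n_jobs=n_jobs)(delayed(one)(q, ss) for q, ss in tasks)

    curves = {}
    for metric in metrics:
        vals = np.array([r[metric] for r in results]).reshape(len(usable), B)
        curves[metric] = pd.DataFrame(vals, index=pd.Index(usable, name="drop_prop"))
    return StabilityCurves(curves, full, skipped, seed)


def cs_coefficient(
    curves: StabilityCurves | pd.DataFrame,
    metric: str = "strength",
    cor_threshold: float = 0.7,
    confidence: float = 0.95,
) -> float:
    """Correlation-stability coefficient from case-dropping curves.

    The largest tested drop proportion q such that at every tested q' <= q at
    least ``confidence`` of the bootstrap correlations are >= ``cor_threshold``;
    0 if no tested proportion qualifies.  NaN correlations (degenerate
    subsample metrics) count as failures.
    """
    frame = curves.correlations[metric] if isinstance(curves, StabilityCurves) else curves
    cs = 0.0
    for q in sorted(frame.index):
        vals = frame.loc[q].to_numpy()
        ok = np.nan_to_num(vals >= cor_threshold, nan=False)
        if ok.mean() >= confidence:
            cs = float(q)
        else:
            break
    return cs


def difference_test_matrix(
    observed: np.ndarray, boots: np.ndarray, alpha: float = 0.05, eps: float = 1e-5
) -> np.ndarray:
    """Symmetric boolean matrix of pairwise bootstrap difference tests.

    ``observed`` is a length-m vector; ``boots`` is B x m.  Pair (a, b) is
    significant when the percentile bootstrap CI of value_a - value_b
    excludes 0 at level ``alpha``.  Differences below ``eps`` — the numerical
    resolution of the glasso solver — are never flagged.  No multiplicity
    correction (the display is exploratory, as is conventional for these
    plots).
    """
    m = len(observed)
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    sig = np.zeros((m, m), dtype=bool)
    for a in range(m):
        for b in range(a + 1, m):
            diff = boots[:, a] - boots[:, b]
            lo_v, hi_v = np.percentile(diff, [lo, hi])
            s = bool(lo_v > eps or hi_v < -eps)
            sig[a, b] = sig[b, a] = s
    return sig


def edge_difference_test(boot: EdgeBootstrap, alpha: float = 0.05):
    """Pairwise difference test over all nonzero observed edges."""
    p = len(boot.node_names)
    iu = list(zip(*np.triu_indices(p, 1)))
    pairs = [(i, j) for i, j in iu if boot.sample_weights[i, j] != 0]
    observed = np.array([boot.sample_weights[i, j] for i, j in pairs])
    draws = np.stack([boot.boot_weights[:, i, j] for i, j in pairs], axis=1)
    labels = [f"{boot.node_names[i]}--{boot.node_names[j]}" for i, j in pairs]
    sig = difference_test_matrix(observed, draws, alpha)
    return pd.DataFrame(sig, index=labels, columns=labels)


def centrality_difference_test(
    boot: EdgeBootstrap, metric: str = "strength", alpha: float = 0.05
):
    """Pairwise node-strength difference test from the edge bootstrap."""
    if metric != "strength":
        raise ValueError("only strength differences are derivable from edge bootstraps")
    observed = np.abs(boot.sample_weights).sum(axis=0)
    draws = np.abs(boot.boot_weights).sum(axis=1)
    sig = difference_test_matrix(observed, draws, alpha)
    return pd.DataFrame(sig, index=boot.node_names, columns=boot.node_names)
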