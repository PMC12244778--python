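"""Node-level network indices: strength, closeness, betweenness, bridge strength, predictability.

Conventions follow the standard psychometric-network toolchain: strength is
the sum of absolute incident edge weights; shortest-path metrics use edge
length 1/|w|; closeness is the inverse of the summed distance to all other
reachable nodes (a flag switches to the inverse-average convention, which
rescales by a constant and leaves rankings unchanged), with nodes in smaller
components penalized by (component size - 1)/(p - 1); betweenness uses the
standard accumulation with fractional credit for tied shortest paths,
unnormalized.  Predictability is the variance share of a node explained by
an ordinary least-squares fit on its network neighbors.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import SymptomDataset
from .errors import ValidationError
from .ggm import SymptomNetwork


def centrality_table(network: SymptomNetwork, closeness_convention: str = "sum") -> pd.DataFrame:
    """Strength, closeness and betweenness for every node.

    Isolated nodes score 0 on all three indices.
    """
    if closeness_convention not in {"sum", "mean"}:
        raise ValidationError("closeness_convention must be 'sum' or 'mean'")
    W = network.weights
    p = network.p
    names = network.node_names
    strength = np.abs(W).sum(axis=0)

    G = network.to_graph()
    closeness = np.zeros(p)
    for i, name in enumerate(names):
        dist = nx.single_source_dijkstra_path_length(G, name, weight="length")
        dist.pop(name, None)
        if not dist:
            continue
        total = sum(dist.values())
        k = len(dist) + 1  # component size
        inv = 1.0 / total if closeness_convention == "sum" else (k - 1) / total
        closeness[i] = inv * (k - 1) / (p - 1) if p > 1 else 0.0

    bet = nx.betweenness_centrality(G, weight="length", normalized=False)
    betweenness = np.array([bet[name] for name in names])

    return pd.DataFrame(
        {
            "node": names,
            "node_class": network.node_classes,
            "strength": strength,
            "closeness": closeness,
            "betweenness": betweenness,
        }
    ).set_index("node")


def bridge_strength(network: SymptomNetwork, cluster_labels: dict | None = None) -> pd.Series:
    """Per-node sum of absolute edge weights to nodes in other clusters.

    Covariate nodes are excluded; every symptom node must carry a cluster
    label.  Edges from a symptom to a covariate node do not count toward its
    bridge strength (bridges are defined between symptom clusters).
    """
    labels = cluster_labels if cluster_labels is not None else network.cluster_labels
    if labels is None:
        raise ValidationError("no cluster labels available for bridge strength")
    symptoms = network.symptom_nodes
    missing = [s for s in symptoms if s not in labels]
    if missing:
        raise ValidationError(f"nodes without a cluster label: {missing}")
    idx = {n: i for i, n in enumerate(network.node_names)}
    W = network.weights
    out = {}
    for s in symptoms:
        i = idx[s]
        total = 0.0
        for t in symptoms:
            if t == s or labels[t] == labels[s]:
                continue
            total += abs(W[i, idx[t]])
        out[s] = total
    return pd.Series(out, name="bridge_strength")


def predictability(
    dataset: SymptomDataset | pd.DataFrame, network: SymptomNetwork
) -> pd.Series:
    """Per-node R^2 from OLS of each node on its network neighbors.

    Nodes without neighbors get 0.  Covariate nodes, when present in the
    network, act as regressors for their neighbors but receive no value of
    their own (rankings are over symptoms).  ``dataset`` may be a plain
    numeric DataFrame whose columns cover the network nodes.
    """
    if isinstance(dataset, pd.DataFrame):
        frames = {c: dataset[c].to_numpy(float) for c in dataset.columns}
        n = dataset.shape[0]
    else:
        frames = {s: dataset.severities[s].to_numpy(float) for s in dataset.symptom_names}
        for c in dataset.covariates.columns:
            if c in network.node_names:
                frames[c] = pd.to_numeric(dataset.covariates[c]).to_numpy(float)
        n = dataset.n
    missing = [nm for nm in network.node_names if nm not in frames]
    if missing:
        raise ValidationError(f"dataset lacks columns for network nodes: {missing}")

    W = network.weights
    names = network.node_names
    out = {}
    for i, name in enumerate(names):
        if network.node_classes[i] != "symptom":
            continue
        nbrs = [names[j] for j in range(network.p) if j != i and W[i, j] != 0]
        if not nbrs:
            out[name] = 0.0
            continue
        if n < len(nbrs) + 2:
            raise ValidationError(
                f"too few rows ({n}) to regress {name!r} on {len(nbrs)} neighbors"
            )
        y = frames[name]
        X = np.column_stack([np.ones(n)] + [frames[b] for b in nbrs])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        tss = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / tss if tss > 0 else 0.0
        out[name] = float(min(max(r2, 0.0), 1.0))
    return pd.Series(out, name="predictability")


def full_centrality(
    dataset: SymptomDataset,
    network: SymptomNetwork,
    cluster_labels: dict | None = None,
    closeness_convention: str = "sum",
) -> pd.DataFrame:
    """Combined centrality table with bridge strength and predictability.

    Adds z-standardized columns (suffix ``_z``) for the indices, computed
    over symptom nodes, as centrality plots conventionally display.
    """
    tab = centrality_table(network, closeness_convention)
    labels = cluster_labels if cluster_labels is not None else network.cluster_labels
    if labels is not None:
        tab["bridge_strength"] = bridge_strength(network, labels)
    tab["predictability"] = predictability(dataset, network)
    sym = tab["node_class"] == "symptom"
    for col in ["strength", "closeness", "betweenness", "bridge_strength"]:
        if col not in tab.columns:
            continue
        v = tab.loc[sym, col]
        sd = v.std(ddof=1)
        tab.loc[sym, col + "_z"] = (v - v.mean()) / sd if sd > 0 else 0.0
    return tab
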