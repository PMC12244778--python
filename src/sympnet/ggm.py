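"""Regularized partial-correlation network estimation.

The contemporaneous symptom network is a Gaussian graphical model estimated
from the Spearman correlation matrix of the ordinal severities: the graphical
lasso is run along a log-spaced penalty path and the penalty is selected by
the extended BIC (EBIC), after which the selected precision matrix is
converted to partial-correlation edge weights.  Covariates can enter the
correlation matrix directly as additional nodes, yielding the
covariate-adjusted network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from ._glasso import glasso_cd, glasso_path, precision_from_w
from .cohort import SymptomDataset
from .errors import ConvergenceError, ValidationError, ZeroVarianceError
from .generate import partial_correlations

EIG_FLOOR = 1e-8


def repair_correlation(R: np.ndarray) -> np.ndarray:
    """Nearest-PD repair: clip eigenvalues at a small floor, rescale to unit diagonal."""
    w, v = np.linalg.eigh(R)
    fixed = (v * np.clip(w, EIG_FLOOR, None)) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    return 0.5 * (fixed + fixed.T)


def correlation_matrix(data: pd.DataFrame | np.ndarray, kind: str = "spearman"):
    """Correlation matrix of the columns, with PD repair when needed.

    Spearman uses average ranks for ties.  Returns (R, repaired_flag).
    """
    X = np.asarray(data, float)
    if X.shape[0] < 3:
        raise ValidationError("need at least 3 rows for a correlation matrix")
    constant = np.where(X.std(axis=0) == 0)[0]
    if len(constant):
        names = (
            [data.columns[i] for i in constant]
            if isinstance(data, pd.DataFrame)
            else list(constant)
        )
        raise ZeroVarianceError(f"constant columns: {names}")
    if kind == "spearman":
        R = spearmanr(X).statistic
        if X.shape[1] == 2:  # spearmanr returns a scalar for two columns
            R = np.array([[1.0, float(R)], [float(R), 1.0]])
    elif kind == "pearson":
        R = np.corrcoef(X, rowvar=False)
    else:
        raise ValidationError(f"unknown correlation kind {kind!r}")
    R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 1.0)
    repaired = False
    if np.linalg.eigvalsh(R).min() <= EIG_FLOOR:
        R = repair_correlation(R)
        repaired = True
    return R, repaired


def glasso_fit(
    S: np.ndarray, lam: float, tol: float = 1e-6, max_iter: int = 10_000
) -> np.ndarray:
    """L1-penalized precision estimate for one penalty value.

    Minimizes -log det(Omega) + tr(S Omega) + lam * sum_{i != j} |omega_ij|
    (penalty on off-diagonal entries only) by block coordinate descent;
    converges when the largest parameter change in a sweep is below ``tol``.
    """
    S = np.asarray(S, float)
    if lam < 0:
        raise ValidationError("penalty must be nonnegative")
    W, B, n_iter, ok = glasso_cd(S, float(lam), float(tol), int(max_iter))
    if not ok:
        raise ConvergenceError(
            f"graphical lasso did not converge in {max_iter} sweeps",
            {"lambda": lam, "n_iter": int(n_iter), "p": S.shape[0]},
        )
    return precision_from_w(W, B)


def ebic(omega: np.ndarray, S: np.ndarray, n: int, gamma: float) -> float:
    """Extended BIC of a precision estimate against sample correlation S.

    EBIC = -2 l(Omega) + E log n + 4 E gamma log p, with
    l = (n/2)(log det Omega - tr(S Omega)) and E the edge count.
    """
    p = omega.shape[0]
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        return np.inf
    ll = 0.5 * n * (logdet - np.trace(S @ omega))
    iu = np.triu_indices(p, 1)
    E = int(np.count_nonzero(omega[iu]))
    return float(-2.0 * ll + E * np.log(n) + 4.0 * E * gamma * np.log(p))


@dataclass
class SymptomNetwork:
    """Signed weighted partial-correlation network over symptom (+ covariate) nodes."""

    node_names: list[str]
    weights: np.ndarray  # symmetric, zero diagonal, entries in (-1, 1)
    node_classes: list[str] = field(default_factory=list)  # 'symptom' | 'covariate'
    cluster_labels: dict[str, object] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        W = self.weights
        p = len(self.node_names)
        if W.shape != (p, p):
            raise ValidationError("weight matrix does not match node count")
        if not np.allclose(W, W.T, atol=1e-10):
            raise ValidationError("weight matrix must be symmetric")
        if np.abs(np.diag(W)).max() > 0:
            raise ValidationError("weight matrix must have zero diagonal")
        if np.abs(W).max() >= 1:
            raise ValidationError("partial-correlation weights must lie in (-1, 1)")
        if not self.node_classes:
            self.node_classes = ["symptom"] * p

    @property
    def p(self) -> int:
        return len(self.node_names)

    @property
    def symptom_nodes(self) -> list[str]:
        return [n for n, c in zip(self.node_names, self.node_classes) if c == "symptom"]

    def global_strength(self) -> float:
        """Sum of absolute edge weights, each edge counted once."""
        iu = np.triu_indices(self.p, 1)
        return float(np.abs(self.weights[iu]).sum())

    def edge_list(self, nonzero_only: bool = True) -> pd.DataFrame:
        rows = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                w = self.weights[i, j]
                if nonzero_only and w == 0:
                    continue
                rows.append(
                    {"node_a": self.node_names[i], "node_b": self.node_names[j], "weight": w}
                )
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])

    def to_graph(self) -> nx.Graph:
        G = nx.Graph()
        for name, cls in zip(self.node_names, self.node_classes):
            G.add_node(name, node_class=cls)
        for i in range(self.p):
            for j in range(i + 1, self.p):
                w = float(self.weights[i, j])
                if w != 0.0:
                    G.add_edge(
                        self.node_names[i],
                        self.node_names[j],
                        weight=w,
                        abs_weight=abs(w),
                        length=1.0 / abs(w),
                    )
        return G

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_graph(), str(path))


def lambda_path(S: np.ndarray, n_lambda: int, lambda_min_ratio: float) -> np.ndarray:
    """Log-spaced decreasing penalty path from max |off-diagonal| of S."""
    p = S.shape[0]
    iu = np.triu_indices(p, 1)
    lam_max = float(np.abs(S[iu]).max())
    if lam_max <= 0:
        lam_max = 1e-4
    return np.exp(np.linspace(np.log(lam_max), np.log(lam_max * lambda_min_ratio), n_lambda))


def estimate_weights(
    X: np.ndarray,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    corr_kind: str = "spearman",
    tol: float = 1e-6,
    max_iter: int = 10_000,
):
    """EBIC-selected glasso partial-correlation weights from a raw data matrix.

    The matrix-level workhorse behind :func:`estimate_network`; also used
    directly inside bootstrap and permutation loops.  Returns
    (weights, meta_dict).
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    R, repaired = correlation_matrix(X, kind=corr_kind)
    lambdas = lambda_path(R, n_lambda, lambda_min_ratio)
    omegas, ok = glasso_path(R, lambdas, float(tol), int(max_iter))
    if not ok.all():
        bad = lambdas[~np.asarray(ok)]
        raise ConvergenceError(
            "graphical lasso failed to converge on the penalty path",
            {"lambdas": bad.tolist()},
        )
    scores = np.array([ebic(omegas[t], R, n, gamma) for t in range(len(lambdas))])
    best = int(np.argmin(scores))
    weights = partial_correlations(omegas[best])
    weights = 0.5 * (weights + weights.T)
    meta = {
        "n": n,
        "gamma": gamma,
        "lambda_selected": float(lambdas[best]),
        "lambda_path": lambdas.tolist(),
        "ebic_path": scores.tolist(),
        "correlation_kind": corr_kind,
        "pd_repaired": repaired,
    }
    return weights, meta


def estimate_network(
    dataset: SymptomDataset,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    covariates: Sequence[str] | None = None,
    corr_kind: str = "spearman",
    cluster_labels: dict | None = None,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> SymptomNetwork:
    """EBIC-selected graphical-lasso network of a symptom dataset.

    ``covariates`` names numerically coded covariate columns to append as
    network nodes (binary 0/1 or ordinal integer coding).  The penalty path
    runs from the largest absolute off-diagonal sample correlation down to
    ``lambda_min_ratio`` times it in ``n_lambda`` log-spaced steps.
    """
    cols = [dataset.severities[s] for s in dataset.symptom_names]
    names = list(dataset.symptom_names)
    classes = ["symptom"] * len(names)
    for c in covariates or []:
        if c not in dataset.covariates.columns:
            raise ValidationError(f"covariate {c!r} not present in the dataset")
        cols.append(pd.to_numeric(dataset.covariates[c]))
        names.append(c)
        classes.append("covariate")
    X = pd.concat(cols, axis=1).to_numpy(float)

    weights, meta = estimate_weights(
        X,
        gamma=gamma,
        n_lambda=n_lambda,
        lambda_min_ratio=lambda_min_ratio,
        corr_kind=corr_kind,
        tol=tol,
        max_iter=max_iter,
    )
    return SymptomNetwork(
        node_names=names,
        weights=weights,
        node_classes=classes,
        cluster_labels=dict(cluster_labels) if cluster_labels else None,
        meta=meta,
    )
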