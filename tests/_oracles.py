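"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (exhaustive enumeration, direct matrix
algebra) kept separate from the library code paths they validate.
"""

import itertools

import numpy as np


def brute_force_paths(W):
    """All-pairs shortest-path distances and path counts by full enumeration.

    Edge length is 1/|w|.  Returns (dist, npaths, paths) where paths[(s, t)]
    lists the node sequences of all shortest s-t paths.
    """
    p = W.shape[0]
    adj = {
        (i, j): 1.0 / abs(W[i, j])
        for i in range(p)
        for j in range(p)
        if i != j and W[i, j] != 0
    }
    dist = np.full((p, p), np.inf)
    np.fill_diagonal(dist, 0.0)
    best_paths = {}
    for s in range(p):
        for t in range(p):
            if s == t:
                continue
            best, paths = np.inf, []
            inner = [v for v in range(p) if v not in (s, t)]
            for r in range(len(inner) + 1):
                for mid in itertools.permutations(inner, r):
                    seq = (s, *mid, t)
                    if any((seq[k], seq[k + 1]) not in adj for k in range(len(seq) - 1)):
                        continue
                    d = sum(adj[(seq[k], seq[k + 1])] for k in range(len(seq) - 1))
                    if d < best - 1e-12:
                        best, paths = d, [seq]
                    elif abs(d - best) <= 1e-12:
                        paths.append(seq)
            dist[s, t] = best
            best_paths[(s, t)] = paths
    return dist, best_paths


def brute_force_centralities(W, closeness_convention="sum"):
    """Closeness and betweenness from exhaustive path enumeration."""
    p = W.shape[0]
    dist, paths = brute_force_paths(W)
    closeness = np.zeros(p)
    for i in range(p):
        finite = [dist[i, j] for j in range(p) if j != i and np.isfinite(dist[i, j])]
        if not finite:
            continue
        total = sum(finite)
        k = len(finite) + 1
        inv = 1.0 / total if closeness_convention == "sum" else (k - 1) / total
        closeness[i] = inv * (k - 1) / (p - 1)
    betweenness = np.zeros(p)
    for (s, t), plist in paths.items():
        if s >= t or not plist:
            continue
        for seq in plist:
            for v in seq[1:-1]:
                betweenness[v] += 1.0 / len(plist)
    return closeness, betweenness


def spearman_rank_oracle(X):
    """Spearman correlation as average ranks followed by Pearson."""
    from scipy.stats import rankdata

    R = np.column_stack([rankdata(X[:, j], method="average") for j in range(X.shape[1])])
    return np.corrcoef(R, rowvar=False)


def varimax_grid_oracle(loadings, step=0.001):
    """Best 2-factor rotation angle by brute-force grid search."""
    from sympnet.factors import varimax_criterion

    best_angle, best_val = 0.0, -np.inf
    for angle in np.arange(0.0, np.pi / 2, step):
        c, s = np.cos(angle), np.sin(angle)
        rotated = loadings @ np.array([[c, -s], [s, c]])
        val = varimax_criterion(rotated)
        if val > best_val:
            best_angle, best_val = angle, val
    return best_angle, best_val


def random_pd_correlation(rng, p, n_factor=3):
    """Random well-conditioned correlation matrix."""
    A = rng.standard_normal((p, n_factor * p))
    S = A @ A.T / (n_factor * p)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)
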