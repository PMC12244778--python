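"""Symptom-cluster extraction by exploratory factor analysis.

Clusters are extracted the classical way for symptom inventories: principal
component analysis of the item correlation matrix, retention of components
with eigenvalue > 1, varimax rotation with Kaiser normalization, and
assignment of each symptom to the factor carrying its largest absolute
rotated loading provided that loading clears a minimum (0.5 by default).
Sampling adequacy is reported through the Kaiser-Meyer-Olkin statistic and
Bartlett's test of sphericity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, spearmanr

from .cohort import SymptomDataset
from .errors import SingularMatrixError, ValidationError, ZeroVarianceError


def adequacy_tests(R: np.ndarray, n: int):
    """KMO sampling adequacy and Bartlett's sphericity test.

    KMO compares squared observed correlations with squared anti-image
    partial correlations obtained from the scaled inverse of R:
    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over i != j.
    Bartlett: chi2 = -(n - 1 - (2p + 5)/6) * ln det R with p(p-1)/2 df.

    Returns (kmo, chi2, df, p_value).
    """
    R = np.asarray(R, float)
    p = R.shape[0]
    if R.shape != (p, p) or not np.allclose(R, R.T, atol=1e-10):
        raise ValidationError("adequacy_tests needs a square symmetric matrix")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValidationError("correlation matrix must have unit diagonal")

    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise SingularMatrixError("correlation matrix is singular or indefinite")
    off = ~np.eye(p, dtype=bool)

    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - slogdet catches first
        raise SingularMatrixError("correlation matrix not invertible") from exc
    d = np.sqrt(np.diag(Rinv))
    Q = -Rinv / np.outer(d, d)  # anti-image partial correlations
    r2 = (R[off] ** 2).sum()
    q2 = (Q[off] ** 2).sum()
    kmo = r2 / (r2 + q2)

    stat = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(chi2.sf(stat, df))
    return float(kmo), float(stat), int(df), pval


def varimax_criterion(loadings: np.ndarray) -> float:
    """Raw varimax criterion: summed column variances of squared loadings."""
    L2 = np.asarray(loadings) ** 2
    p = L2.shape[0]
    return float((L2**2).mean(axis=0).sum() - (L2.mean(axis=0) ** 2).sum()) * p


def varimax(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    tol: float = 1e-10,
    max_sweeps: int = 1000,
):
    """Varimax rotation by pairwise planar rotations.

    Rows are optionally normalized by their communalities before rotation
    (Kaiser normalization) and denormalized afterwards.  Sweeps over all
    factor pairs continue until the varimax criterion changes by less than
    ``tol`` or ``max_sweeps`` is reached.  Returns (rotated_loadings,
    rotation_matrix) with loadings = unrotated @ rotation.
    """
    A = np.array(loadings, float)
    p, k = A.shape
    if k < 2:
        return A, np.eye(k)
    h = np.sqrt((A**2).sum(axis=1))
    if kaiser_normalize:
        safe = np.where(h > 0, h, 1.0)
        A = A / safe[:, None]
    T = np.eye(k)
    crit = varimax_criterion(A)
    for _ in range(max_sweeps):
        for a in range(k - 1):
            for b in range(a + 1, k):
                x, y = A[:, a], A[:, b]
                u = x**2 - y**2
                v = 2 * x * y
                num = 2 * (p * (u * v).sum() - u.sum() * v.sum())
                den = p * (u**2 - v**2).sum() - (u.sum() ** 2 - v.sum() ** 2)
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-15:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                rot = np.array([[c, -s], [s, c]])
                A[:, [a, b]] = A[:, [a, b]] @ rot
                T[:, [a, b]] = T[:, [a, b]] @ rot
        new_crit = varimax_criterion(A)
        if new_crit - crit < tol:
            break
        crit = new_crit
    if kaiser_normalize:
        A = A * np.where(h > 0, h, 1.0)[:, None]
    return A, T


@dataclass
class ClusterSolution:
    """Factor-analytic symptom-cluster solution."""

    eigenvalues: np.ndarray
    n_factors: int
    loadings: pd.DataFrame  # symptoms x factors, rotated
    explained_variance: np.ndarray  # per retained factor, percent (pre-rotation)
    cumulative_variance: np.ndarray
    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    assignments: dict[str, int]
    unassigned: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {f: [] for f in range(self.n_factors)}
        for s, f in self.assignments.items():
            out[f].append(s)
        return out

    def to_table(self) -> pd.DataFrame:
        tab = self.loadings.copy()
        tab["assignment"] = [
            self.assignments.get(s, -1) for s in tab.index
        ]
        return tab


def extract_clusters(
    dataset: SymptomDataset,
    min_loading: float = 0.5,
    corr: str = "pearson",
    kaiser_normalize: bool = True,
) -> ClusterSolution:
    """PCA extraction + varimax rotation + loading-gated cluster assignment.

    Retains components with eigenvalue > 1 from the item correlation matrix,
    rotates their loadings with varimax, resolves sign indeterminacy by
    forcing each factor's largest-|loading| entry positive, and assigns each
    symptom to the factor of its maximal absolute rotated loading when that
    loading exceeds ``min_loading``.
    """
    X = dataset.severities.to_numpy(float)
    variances = X.var(axis=0)
    dead = [s for s, v in zip(dataset.symptom_names, variances) if v == 0]
    if dead:
        raise ZeroVarianceError(f"zero-variance symptom columns: {dead}")
    if corr == "pearson":
        R = np.corrcoef(X, rowvar=False)
    elif corr == "spearman":
        R = spearmanr(X).statistic
    else:
        raise ValidationError(f"unknown correlation kind {corr!r}")

    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_factors = max(int((eigval > 1.0).sum()), 1)
    raw = eigvec[:, :n_factors] * np.sqrt(eigval[:n_factors])

    rotated, _ = varimax(raw, kaiser_normalize=kaiser_normalize)
    # sign convention: each factor's largest-|loading| entry is positive
    for j in range(n_factors):
        lead = np.argmax(np.abs(rotated[:, j]))
        if rotated[lead, j] < 0:
            rotated[:, j] = -rotated[:, j]

    p = R.shape[0]
    explained = eigval[:n_factors] / p * 100.0
    cumulative = np.cumsum(eigval / p * 100.0)[:n_factors]
    kmo, b_chi2, b_df, b_p = adequacy_tests(R, dataset.n)

    names = dataset.symptom_names
    assignments, unassigned = {}, []
    for i, s in enumerate(names):
        j = int(np.argmax(np.abs(rotated[i])))
        if abs(rotated[i, j]) > min_loading:
            assignments[s] = j
        else:
            unassigned.append(s)
    warnings = []
    counts = pd.Series(list(assignments.values())).value_counts() if assignments else pd.Series(dtype=int)
    for f in range(n_factors):
        if counts.get(f, 0) < 2:
            warnings.append(f"factor {f} has fewer than 2 assigned symptoms")

    return ClusterSolution(
        eigenvalues=eigval,
        n_factors=n_factors,
        loadings=pd.DataFrame(
            rotated, index=names, columns=[f"factor_{j}" for j in range(n_factors)]
        ),
        explained_variance=explained,
        cumulative_variance=cumulative,
        kmo=kmo,
        bartlett_chi2=b_chi2,
        bartlett_df=b_df,
        bartlett_p=b_p,
        assignments=assignments,
        unassigned=unassigned,
        warnings=warnings,
    )
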