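"""Synthetic cohorts with planted network structure.

A cohort is generated from a latent Gaussian graphical model: a sparse
precision matrix realizes the requested within-cluster and bridge partial
correlations, latent multivariate-normal vectors are drawn from it, covariate
effects shift latent means, and each latent value is mapped to an ordinal
0-10 severity by thresholding.  Zero inflation and severity come from a
single latent variable: a participant scores 0 when their latent value falls
below the (1 - prevalence)-quantile of the marginal, and otherwise the upper
tail is cut into equal-probability bins giving severities 1..severity_max.
This preserves the monotone latent-severity link that a Spearman-based
network model assumes.

``study_like_config`` returns a generator configuration calibrated to the
reference immunotherapy lung-cancer cohort: 249 participants, 19 symptoms
(two of them below the 20% prevalence filter), four symptom clusters, bridge
partial correlations centered on sadness, and covariate effects for gender,
smoking history and education.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import reference
from .cohort import SymptomDataset
from .errors import NotPositiveDefiniteError, ValidationError

EIG_FLOOR = 1e-8


@dataclass
class GeneratorConfig:
    """Everything needed to draw one synthetic cohort.

    ``cluster_spec`` maps cluster name -> symptom names and must cover every
    symptom exactly once; ``bridge_edges`` plants cross-cluster partial
    correlations as (symptom_a, symptom_b, pcor) triples.  Covariates are
    drawn independently of one another: a float in ``covariate_prevalence``
    means a binary covariate, a tuple of probabilities an ordinal one with
    levels 0..k-1; ``covariate_effects`` gives per-symptom latent mean shifts
    applied per unit of the coded covariate level.
    """

    n_participants: int
    cluster_spec: dict[str, list[str]]
    target_prevalence: dict[str, float]
    intra_cluster_pcor: float = 0.2
    bridge_edges: list[tuple[str, str, float]] = field(default_factory=list)
    severity_max: int = 10
    covariate_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    covariate_prevalence: dict[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_participants <= 0:
            raise ValidationError("n_participants must be positive")
        if not -1 < self.intra_cluster_pcor < 1:
            raise ValidationError("intra_cluster_pcor must lie in (-1, 1)")
        for a, b, r in self.bridge_edges:
            if not -1 < r < 1:
                raise ValidationError(f"bridge pcor {r} for ({a}, {b}) not in (-1, 1)")
        seen: list[str] = []
        for members in self.cluster_spec.values():
            seen.extend(members)
        if len(seen) != len(set(seen)):
            raise ValidationError("cluster_spec assigns a symptom twice")
        for s, p in self.target_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"prevalence for {s!r} outside [0, 1]")
        missing = set(seen) - set(self.target_prevalence)
        if missing:
            raise ValidationError(f"no target prevalence for {sorted(missing)}")

    @property
    def symptom_names(self) -> list[str]:
        names: list[str] = []
        for members in self.cluster_spec.values():
            names.extend(members)
        return names

    @property
    def cluster_labels(self) -> dict[str, str]:
        return {s: c for c, members in self.cluster_spec.items() for s in members}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        raw = json.loads(Path(path).read_text())
        raw["bridge_edges"] = [tuple(e) for e in raw.get("bridge_edges", [])]
        raw["covariate_prevalence"] = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.get("covariate_prevalence", {}).items()
        }
        return cls(**raw)


def build_true_network(config: GeneratorConfig):
    """Precision and partial-correlation matrices implied by the config.

    The precision matrix has unit diagonal and off-diagonal entries
    -pcor for every requested within-cluster and bridge edge; everything
    else is exactly zero.  If the result is not positive definite it is
    repaired by eigenvalue clipping and rescaling to unit diagonal; if the
    repair moves any requested partial correlation by more than 1e-6 the
    offending edges are reported in a NotPositiveDefiniteError.
    """
    names = config.symptom_names
    p = len(names)
    idx = {s: i for i, s in enumerate(names)}
    omega = np.eye(p)
    requested: dict[tuple[int, int], float] = {}
    for members in config.cluster_spec.values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                i, j = idx[members[a]], idx[members[b]]
                requested[(min(i, j), max(i, j))] = config.intra_cluster_pcor
    for a, b, r in config.bridge_edges:
        if a not in idx or b not in idx:
            raise ValidationError(f"bridge edge ({a}, {b}) names an unknown symptom")
        i, j = idx[a], idx[b]
        requested[(min(i, j), max(i, j))] = r
    for (i, j), r in requested.items():
        omega[i, j] = omega[j, i] = -r

    repaired = False
    eigval = np.linalg.eigvalsh(omega)
    if eigval.min() <= EIG_FLOOR:
        repaired = True
        w, v = np.linalg.eigh(omega)
        omega = (v * np.clip(w, EIG_FLOOR, None)) @ v.T
        d = np.sqrt(np.diag(omega))
        omega = omega / np.outer(d, d)

    pcor = partial_correlations(omega)
    if repaired:
        bad = [
            (names[i], names[j], r, pcor[i, j])
            for (i, j), r in requested.items()
            if abs(pcor[i, j] - r) > 1e-6
        ]
        if bad:
            desc = ", ".join(f"{a}-{b} (wanted {r:.3f}, got {got:.3f})" for a, b, r, got in bad)
            raise NotPositiveDefiniteError(
                f"requested partial correlations are not jointly realizable: {desc}",
                [(a, b) for a, b, _, _ in bad],
            )
    return omega, pcor


def partial_correlations(omega: np.ndarray) -> np.ndarray:
    """Partial correlations -omega_ij / sqrt(omega_ii omega_jj), zero diagonal."""
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 0.0)
    return pcor


def _severity_cuts(prevalence: float, severity_max: int) -> np.ndarray:
    """Latent cut points: below the first cut is severity 0, then equal bins."""
    if prevalence <= 0.0:
        return np.full(severity_max, np.inf)
    if prevalence >= 1.0:
        qs = np.linspace(0.0, 1.0, severity_max + 1)[1:-1]
        return np.concatenate([[-np.inf], norm.ppf(qs)])
    qs = 1.0 - prevalence + prevalence * np.arange(severity_max) / severity_max
    return norm.ppf(qs)


def sample_dataset(config: GeneratorConfig) -> SymptomDataset:
    """Draw one cohort: latent MVN -> covariate shifts -> ordinal thresholding.

    Deterministic given (config, seed); same seed and config give a
    bit-identical dataset.
    """
    omega, _ = build_true_network(config)
    sigma = np.linalg.inv(omega)
    d = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(d, d)

    names = config.symptom_names
    n, p = config.n_participants, len(names)
    rng = np.random.default_rng(config.seed)

    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, p)) @ chol.T

    covariates = {}
    for cov_name, prev in config.covariate_prevalence.items():
        if isinstance(prev, (tuple, list)):
            probs = np.asarray(prev, float)
            levels = rng.choice(len(probs), size=n, p=probs / probs.sum())
        else:
            levels = (rng.random(n) < float(prev)).astype(int)
        covariates[cov_name] = levels
        effects = config.covariate_effects.get(cov_name, {})
        for s, shift in effects.items():
            if s in names:
                z[:, names.index(s)] += shift * levels

    severities = np.empty((n, p), dtype=int)
    for j, s in enumerate(names):
        cuts = _severity_cuts(config.target_prevalence[s], config.severity_max)
        severities[:, j] = np.searchsorted(cuts, z[:, j], side="right")

    return SymptomDataset(
        pd.DataFrame(severities, columns=names),
        pd.DataFrame(covariates),
        {"generator": "latent-gaussian-threshold", "seed": config.seed},
    )


def study_like_config(seed: int = 0, n_participants: int = reference.N_ANALYZED) -> GeneratorConfig:
    """Generator configuration calibrated to the reference cohort.

    249 participants, the 19 inventory symptoms with their published
    occurrence fractions (drowsiness and cough-with-blood below the 20%
    filter), four symptom clusters, bridges sadness-fatigue, sadness-cough
    and sadness-nausea, and covariate effects mirroring the published
    associations (female: higher emotional/fatigue burden; smoking history:
    lower cough and sadness scores; education: weak negative shifts).
    """
    return GeneratorConfig(
        n_participants=n_participants,
        cluster_spec={k: list(v) for k, v in reference.CLUSTER_SPEC.items()},
        target_prevalence=dict(reference.TARGET_PREVALENCE),
        intra_cluster_pcor=0.18,
        bridge_edges=[
            ("sadness", "fatigue", 0.40),
            ("sadness", "cough", 0.25),
            ("sadness", "nausea", 0.22),
        ],
        covariate_effects={
            "female": {
                "sadness": 0.70,
                "fatigue": 0.70,
                "numbness": 0.60,
                "distress": 0.50,
                "restless sleep": 0.50,
                "pain": 0.40,
                "xerostomia": 0.40,
                "forgetfulness": 0.40,
                "nausea": 0.30,
                "insomnia": 0.30,
            },
            "smoking": {
                "cough": -0.70,
                "sadness": -0.60,
                "phlegm": -0.60,
                "chest distress": -0.50,
                "shortness of breath": -0.50,
                "fatigue": -0.40,
                "distress": -0.40,
                "loss of appetite": -0.30,
                "nausea": -0.30,
                "weight loss": -0.30,
            },
            "education": {
                "sadness": -0.30,
                "distress": -0.30,
                "forgetfulness": -0.25,
                "restless sleep": -0.25,
                "insomnia": -0.20,
                "fatigue": -0.20,
            },
        },
        covariate_prevalence=dict(reference.COVARIATE_PREVALENCE),
        seed=seed,
    )
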