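"""Cohort tables: loading, validation, descriptives and the covariate screen.

The universal input of the pipeline is a participants x symptoms table of
integer severities on a 0-10 scale plus categorical covariate columns.  This
module reads and validates such tables, computes prevalence/severity
descriptives and Cronbach's alpha, applies the minimum-prevalence filter that
precedes clustering and network estimation, and runs the multiple linear
regression screen that selects covariates carried into the adjusted network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    AllSymptomsDroppedError,
    RankDeficientError,
    SchemaError,
    ValidationError,
    ZeroVarianceError,
)

log = logging.getLogger(__name__)

SEVERITY_MIN = 0
SEVERITY_MAX = 10


@dataclass
class DatasetSchema:
    """Names the symptom and covariate columns of an input table."""

    symptoms: Sequence[str]
    covariates: Sequence[str] = ()
    id_column: str | None = "id"


@dataclass
class SymptomDataset:
    """Validated participants x symptoms severity matrix with covariates.

    ``severities`` holds integers in [0, 10]; ``covariates`` is an aligned
    frame of categorical/ordinal columns (may be empty); ``provenance``
    records free-text metadata such as exclusion counts.
    """

    severities: pd.DataFrame
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        sev = self.severities
        if sev.shape[1] < 2:
            raise ValidationError("a dataset needs at least 2 symptom columns")
        if sev.shape[0] < 3:
            raise ValidationError("a dataset needs at least 3 participants")
        if sev.isna().any().any():
            raise ValidationError("severity matrix contains missing values")
        vals = sev.to_numpy()
        if vals.min() < SEVERITY_MIN or vals.max() > SEVERITY_MAX:
            raise ValidationError(
                f"severities outside [{SEVERITY_MIN}, {SEVERITY_MAX}]"
            )
        if len(self.covariates) and len(self.covariates) != len(sev):
            raise ValidationError("covariate rows do not align with severities")

    @property
    def n(self) -> int:
        return self.severities.shape[0]

    @property
    def p(self) -> int:
        return self.severities.shape[1]

    @property
    def symptom_names(self) -> list[str]:
        return list(self.severities.columns)

    def total_score(self, items: Sequence[str] | None = None) -> pd.Series:
        """Per-participant unweighted sum of item scores (all items by default)."""
        cols = list(items) if items is not None else self.symptom_names
        return self.severities[cols].sum(axis=1)

    def subset_rows(self, index) -> "SymptomDataset":
        return SymptomDataset(
            self.severities.iloc[index].reset_index(drop=True),
            self.covariates.iloc[index].reset_index(drop=True)
            if len(self.covariates)
            else pd.DataFrame(),
            dict(self.provenance),
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.severities.copy()
        for c in self.covariates.columns:
            out[c] = self.covariates[c].to_numpy()
        out.insert(0, "id", np.arange(1, self.n + 1))
        return out

    def write(self, path: str | Path) -> None:
        """Write the dataset as CSV or XLSX depending on the suffix."""
        path = Path(path)
        frame = self.to_frame()
        if path.suffix.lower() in {".xlsx", ".xls"}:
            frame.to_excel(path, index=False)
        else:
            frame.to_csv(path, index=False)


def load_dataset(path: str | Path, schema: DatasetSchema) -> SymptomDataset:
    """Read and validate a cohort table.

    Rows with any missing symptom item are dropped; the number dropped is
    recorded in ``provenance['n_excluded']`` and logged.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    if path.suffix.lower() in {".xlsx", ".xls"}:
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path)
    if raw.empty:
        raise SchemaError(f"input file is empty: {path}")

    missing = [c for c in [*schema.symptoms, *schema.covariates] if c not in raw.columns]
    if missing:
        raise SchemaError(f"columns named in the schema are absent: {missing}")

    sev = raw[list(schema.symptoms)].apply(pd.to_numeric, errors="coerce")
    complete = sev.notna().all(axis=1)
    n_excluded = int((~complete).sum())
    if n_excluded:
        log.info("excluded %d rows with incomplete symptom items", n_excluded)
    sev = sev.loc[complete].reset_index(drop=True)
    bad = sev[(sev < SEVERITY_MIN) | (sev > SEVERITY_MAX)].stack()
    if len(bad):
        raise ValidationError(
            f"severities outside [{SEVERITY_MIN}, {SEVERITY_MAX}] at {list(bad.index[:5])}"
        )
    cov = (
        raw.loc[complete, list(schema.covariates)].reset_index(drop=True)
        if schema.covariates
        else pd.DataFrame()
    )
    return SymptomDataset(
        sev.astype(int),
        cov,
        {"source": str(path), "n_excluded": n_excluded, "n_loaded": int(complete.sum())},
    )


def descriptives(dataset: SymptomDataset, items: Sequence[str] | None = None):
    """Per-symptom prevalence and severity table plus the total-score summary.

    Returns ``(table, (total_mean, total_sd))`` where the table has one row per
    symptom with columns n_present, prevalence, mean_severity, sd_severity.
    Prevalence is the exact fraction of participants with severity > 0; means
    and SDs are over all participants, zeros included (SD uses n-1).
    """
    n = dataset.n
    sev = dataset.severities
    rows = []
    for name in dataset.symptom_names:
        col = sev[name].to_numpy(float)
        n_present = int((col > 0).sum())
        rows.append(
            {
                "symptom": name,
                "n_present": n_present,
                "prevalence": n_present / n,
                "mean_severity": col.mean(),
                "sd_severity": col.std(ddof=1),
            }
        )
    total = dataset.total_score(items)
    return pd.DataFrame(rows), (float(total.mean()), float(total.std(ddof=1)))


def cronbach_alpha(severities: pd.DataFrame | np.ndarray) -> float:
    """Cronbach's alpha, the classical internal-consistency coefficient.

    alpha = k/(k-1) * (1 - sum of item variances / variance of the item sum),
    with sample variances (denominator n-1).
    """
    X = np.asarray(severities, float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValidationError("Cronbach's alpha needs >= 2 items")
    if X.shape[0] < 3:
        raise ValidationError("Cronbach's alpha needs >= 3 rows")
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ZeroVarianceError("total score has zero variance; alpha undefined")
    item_var = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def filter_by_prevalence(dataset: SymptomDataset, threshold: float = 0.20):
    """Drop symptom columns whose prevalence falls below ``threshold``.

    The comparison is strict (prevalence < threshold drops); returns the
    filtered dataset and the list of dropped symptom names.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"prevalence threshold must be in [0, 1], got {threshold}")
    table, _ = descriptives(dataset)
    keep = table.loc[table["prevalence"] >= threshold, "symptom"].tolist()
    dropped = [s for s in dataset.symptom_names if s not in keep]
    if not keep:
        raise AllSymptomsDroppedError(
            f"threshold {threshold} drops every symptom column"
        )
    filtered = SymptomDataset(
        dataset.severities[keep].copy(),
        dataset.covariates.copy(),
        {**dataset.provenance, "prevalence_threshold": threshold, "dropped": dropped},
    )
    return filtered, dropped


@dataclass
class RegressionScreen:
    """OLS screen of total severity on dummy-coded covariates."""

    terms: pd.DataFrame  # term, level, beta, std_beta, se, t, p, flagged
    r2: float
    adj_r2: float
    f_stat: float
    model_p: float
    reference_levels: dict
    p_threshold: float

    @property
    def flagged_covariates(self) -> list[str]:
        """Covariates with at least one level passing the confounder threshold."""
        hit = self.terms.loc[self.terms["flagged"], "covariate"]
        return sorted(set(hit))


def covariate_screen(
    dataset: SymptomDataset,
    outcome_items: Sequence[str] | None = None,
    reference_levels: dict | None = None,
    p_threshold: float = 0.05,
) -> RegressionScreen:
    """Multiple linear regression of total symptom severity on covariates.

    Each covariate is dummy coded against its reference level (the first
    observed level unless ``reference_levels`` names one).  Rows with missing
    covariates are dropped for the screen only.  Terms with p below
    ``p_threshold`` are flagged as network confounders.
    """
    if dataset.covariates.shape[1] < 2:
        raise ValidationError("covariate screen needs >= 2 covariates")
    cov = dataset.covariates.copy()
    y_all = dataset.total_score(outcome_items).to_numpy(float)
    complete = cov.notna().all(axis=1).to_numpy()
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("covariate screen: dropped %d rows with missing covariates", n_dropped)
    cov = cov.loc[complete]
    y = y_all[complete]

    reference_levels = dict(reference_levels or {})
    cols, names = [], []
    for c in cov.columns:
        levels = sorted(pd.unique(cov[c]))
        ref = reference_levels.setdefault(c, levels[0])
        if ref not in levels:
            raise ValidationError(f"reference level {ref!r} not observed for {c!r}")
        for lev in levels:
            if lev == ref:
                continue
            cols.append((cov[c] == lev).to_numpy(float))
            names.append((c, lev))
    X = np.column_stack(cols)
    if len(y) < X.shape[1] + 2:
        raise ValidationError("too few rows for the number of dummy terms")
    design = sm.add_constant(X)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        aliased = _aliased_terms(design, names)
        raise RankDeficientError(
            f"design matrix is rank deficient; aliased terms: {aliased}", aliased
        )
    fit = sm.OLS(y, design).fit()
    sd_y = y.std(ddof=1)
    rows = []
    for i, (c, lev) in enumerate(names, start=1):
        beta = fit.params[i]
        rows.append(
            {
                "covariate": c,
                "level": lev,
                "beta": beta,
                "std_beta": beta * X[:, i - 1].std(ddof=1) / sd_y if sd_y > 0 else np.nan,
                "se": fit.bse[i],
                "t": fit.tvalues[i],
                "p": fit.pvalues[i],
                "flagged": bool(fit.pvalues[i] < p_threshold),
            }
        )
    return RegressionScreen(
        terms=pd.DataFrame(rows),
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        f_stat=float(fit.fvalue),
        model_p=float(fit.f_pvalue),
        reference_levels=reference_levels,
        p_threshold=p_threshold,
    )


def _aliased_terms(design: np.ndarray, names: list) -> list:
    """Greedily identify columns that add no rank to the design."""
    aliased = []
    base = design[:, :1]
    for i, nm in enumerate(names, start=1):
        cand = np.column_stack([base, design[:, i]])
        if np.linalg.matrix_rank(cand) == base.shape[1]:
            aliased.append(nm)
        else:
            base = cand
    return aliased
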