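"""Cohort I/O, descriptives, Cronbach's alpha, prevalence filter, covariate screen."""

import numpy as np
import pandas as pd
import pytest

from sympnet import (
    DatasetSchema,
    SymptomDataset,
    covariate_screen,
    cronbach_alpha,
    descriptives,
    filter_by_prevalence,
    load_dataset,
)
from sympnet.errors import (
    AllSymptomsDroppedError,
    RankDeficientError,
    SchemaError,
    ValidationError,
    ZeroVarianceError,
)


def _toy_frame(n=6, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "a": rng.integers(0, 11, n),
            "b": rng.integers(0, 11, n),
            "grp": rng.integers(0, 2, n),
        }
    )


SCHEMA = DatasetSchema(symptoms=["a", "b"], covariates=["grp"])


class TestLoadDataset:
    @pytest.mark.parametrize("suffix", [".csv", ".xlsx"])
    def test_write_load_roundtrip(self, tmp_path, suffix):
        ds = SymptomDataset(
            _toy_frame()[["a", "b"]], _toy_frame()[["grp"]]
        )
        path = tmp_path / ("cohort" + suffix)
        ds.write(path)
        back = load_dataset(path, SCHEMA)
        assert back.severities.equals(ds.severities)
        assert (back.covariates["grp"] == ds.covariates["grp"]).all()

    def test_missing_item_row_dropped_and_counted(self, tmp_path):
        frame = _toy_frame(8)
        frame.loc[3, "b"] = np.nan
        path = tmp_path / "cohort.csv"
        frame.to_csv(path, index=False)
        ds = load_dataset(path, SCHEMA)
        assert ds.n == 7
        assert ds.provenance["n_excluded"] == 1

    def test_incomplete_recall_cohort(self, tmp_path):
        """286 recruited rows with 37 incomplete yield an analyzed n of 249."""
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(
            {
                "id": np.arange(286),
                "a": rng.integers(0, 11, 286).astype(float),
                "b": rng.integers(0, 11, 286).astype(float),
                "grp": rng.integers(0, 2, 286),
            }
        )
        frame.loc[frame.index[:37], "a"] = np.nan
        path = tmp_path / "recruited.csv"
        frame.to_csv(path, index=False)
        ds = load_dataset(path, SCHEMA)
        assert ds.n == 249
        assert ds.provenance["n_excluded"] == 37

    def test_unknown_columns_and_out_of_range(self, tmp_path):
        path = tmp_path / "cohort.csv"
        _toy_frame().to_csv(path, index=False)
        with pytest.raises(SchemaError):
            load_dataset(path, DatasetSchema(symptoms=["a", "nope"]))
        bad = _toy_frame()
        bad.loc[0, "a"] = 11
        bad.to_csv(path, index=False)
        with pytest.raises(ValidationError):
            load_dataset(path, SCHEMA)


class TestDescriptives:
    def test_hand_worked_fixture(self):
        sev = pd.DataFrame({"a": [0, 2, 4, 6], "b": [0, 0, 0, 5]})
        ds = SymptomDataset(sev)
        table, (tmean, tsd) = descriptives(ds)
        a = table.set_index("symptom").loc["a"]
        assert a["n_present"] == 3
        assert a["prevalence"] == pytest.approx(0.75)
        assert a["mean_severity"] == pytest.approx(3.0)
        assert a["sd_severity"] == pytest.approx(np.sqrt(20 / 3))
        assert tmean == pytest.approx(np.mean([0, 2, 4, 11]))

    def test_all_zero_column(self):
        ds = SymptomDataset(pd.DataFrame({"a": [0, 0, 0], "b": [1, 2, 3]}))
        row = descriptives(ds)[0].set_index("symptom").loc["a"]
        assert row["prevalence"] == 0 and row["mean_severity"] == 0 and row["sd_severity"] == 0

    def test_prevalence_times_n_is_exact_count(self, study_ds):
        table, _ = descriptives(study_ds)
        counts = table["prevalence"].to_numpy() * study_ds.n
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-12)

    def test_reference_counts_reproduce_printed_percentages(self, reference_counts_ds):
        table = descriptives(reference_counts_ds)[0].set_index("symptom")
        assert round(100 * table.loc["cough", "prevalence"], 1) == 81.9
        assert round(100 * table.loc["cough with blood", "prevalence"], 1) == 15.3


class TestCronbachAlpha:
    def test_identical_items_give_one(self):
        col = np.array([1, 4, 2, 7, 5], float)
        X = np.column_stack([col, col, col])
        assert cronbach_alpha(X) == pytest.approx(1.0)

    @pytest.mark.parametrize("k,rho", [(3, 0.4), (5, 0.7), (10, 0.2)])
    def test_spearman_brown_closed_form(self, k, rho):
        """Equicorrelated items: alpha = k rho / (1 + (k-1) rho) exactly."""
        rng = np.random.default_rng(k)
        n = 60
        raw = rng.standard_normal((n, k))
        raw -= raw.mean(axis=0)
        # whiten empirically, then color so the *sample* correlation is exact
        cov = np.cov(raw, rowvar=False)
        w, v = np.linalg.eigh(cov)
        white = raw @ v @ np.diag(w**-0.5) @ v.T
        target = (1 - rho) * np.eye(k) + rho * np.ones((k, k))
        tw, tv = np.linalg.eigh(target)
        X = white @ tv @ np.diag(np.sqrt(tw)) @ tv.T
        expected = k * rho / (1 + (k - 1) * rho)
        assert cronbach_alpha(X) == pytest.approx(expected, abs=1e-9)

    def test_hand_worked_fixture(self):
        X = np.array([[1, 2, 3], [2, 4, 4], [3, 3, 5], [4, 5, 8], [5, 6, 9]], float)
        assert cronbach_alpha(X) == pytest.approx(300 / 317, abs=1e-12)

    def test_matches_pingouin(self, study_ds):
        pingouin = pytest.importorskip("pingouin")
        expected = pingouin.cronbach_alpha(data=study_ds.severities)[0]
        assert cronbach_alpha(study_ds.severities) == pytest.approx(expected, abs=1e-10)

    def test_zero_total_variance_error(self):
        X = np.array([[1, 2], [2, 1], [0, 3], [3, 0]], float)
        with pytest.raises(ZeroVarianceError):
            cronbach_alpha(X)


class TestPrevalenceFilter:
    def test_reference_counts_retain_17(self, reference_counts_ds):
        filtered, dropped = filter_by_prevalence(reference_counts_ds, 0.20)
        assert filtered.p == 17
        assert set(dropped) == {"drowsiness", "cough with blood"}

    def test_threshold_zero_retains_all(self, reference_counts_ds):
        filtered, dropped = filter_by_prevalence(reference_counts_ds, 0.0)
        assert filtered.p == 19 and dropped == []

    def test_threshold_above_one_rejected(self, reference_counts_ds):
        with pytest.raises(ValidationError):
            filter_by_prevalence(reference_counts_ds, 1.01)

    def test_all_dropped_is_typed_error(self, reference_counts_ds):
        with pytest.raises(AllSymptomsDroppedError):
            filter_by_prevalence(reference_counts_ds, 0.9)

    def test_idempotent(self, study_ds):
        once, _ = filter_by_prevalence(study_ds, 0.20)
        twice, dropped = filter_by_prevalence(once, 0.20)
        assert dropped == []
        assert twice.severities.equals(once.severities)


class TestCovariateScreen:
    def _dataset(self, rng, n, shift=0.0):
        g = rng.integers(0, 2, n)
        base = rng.integers(0, 6, (n, 2))
        sev = base.copy()
        noise = rng.normal(0, 1, n)
        sev[:, 0] = np.clip(np.round(base[:, 0] + shift * g + noise), 0, 10)
        cov = pd.DataFrame({"grp": g, "other": rng.integers(0, 2, n)})
        return SymptomDataset(pd.DataFrame(sev, columns=["a", "b"]), cov)

    def test_null_covariate_rarely_flagged(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ds = self._dataset(rng, 2000, shift=0.0)
            screen = covariate_screen(ds)
            term = screen.terms.set_index("covariate").loc["grp"]
            hits += term["p"] > 0.05
        assert hits >= 90

    def test_planted_shift_always_flagged(self):
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            ds = self._dataset(rng, 500, shift=5.0)
            screen = covariate_screen(ds)
            assert "grp" in screen.flagged_covariates

    def test_outcome_equal_to_dummy_gives_r2_one(self):
        g = np.array([0, 1] * 10)
        sev = pd.DataFrame({"a": g * 5, "b": np.zeros(20, int)})
        cov = pd.DataFrame({"grp": g, "other": (np.arange(20) // 2) % 2})
        ds = SymptomDataset(sev, cov)
        screen = covariate_screen(ds)
        assert screen.r2 == pytest.approx(1.0)

    def test_matches_normal_equations(self, study_ds):
        screen = covariate_screen(study_ds)
        y = study_ds.total_score().to_numpy(float)
        cov = study_ds.covariates
        cols = []
        for c in cov.columns:
            for lev in sorted(pd.unique(cov[c]))[1:]:
                cols.append((cov[c] == lev).to_numpy(float))
        X = np.column_stack([np.ones(len(y))] + cols)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(screen.terms["beta"].to_numpy(), beta[1:], atol=1e-8)

    def test_rank_deficient_names_aliased_terms(self):
        g = np.array([0, 1] * 10)
        sev = pd.DataFrame({"a": g + 1, "b": np.arange(20) % 3})
        cov = pd.DataFrame({"grp": g, "copy": g})
        with pytest.raises(RankDeficientError) as exc:
            covariate_screen(SymptomDataset(sev, cov))
        assert exc.value.aliased_terms
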