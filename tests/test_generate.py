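"""Synthetic cohort generator: planted network, thresholding, determinism."""

import numpy as np
import pytest
from scipy.stats import binom, norm, spearmanr

from sympnet import (
    GeneratorConfig,
    build_true_network,
    partial_correlations,
    sample_dataset,
    study_like_config,
)
from sympnet.errors import NotPositiveDefiniteError, ValidationError
from sympnet import reference

from conftest import two_cluster_config


class TestBuildTrueNetwork:
    def test_block_diagonal_without_bridges(self):
        cfg = GeneratorConfig(
            n_participants=10,
            cluster_spec={"a": ["x1", "x2"], "b": ["y1", "y2"]},
            target_prevalence={s: 0.5 for s in ["x1", "x2", "y1", "y2"]},
            intra_cluster_pcor=0.3,
        )
        _, pcor = build_true_network(cfg)
        assert pcor[0, 1] == pytest.approx(0.3)
        assert pcor[2, 3] == pytest.approx(0.3)
        off_block = pcor[np.ix_([0, 1], [2, 3])]
        assert np.all(off_block == 0.0)

    def test_zero_pcor_gives_identity_precision(self):
        cfg = two_cluster_config(pcor=0.0)
        omega, pcor = build_true_network(cfg)
        np.testing.assert_array_equal(omega, np.eye(6))
        assert np.all(pcor == 0.0)

    def test_matches_inversion_oracle_on_random_config(self):
        rng = np.random.default_rng(3)
        names = [f"v{i}" for i in range(8)]
        cfg = GeneratorConfig(
            n_participants=10,
            cluster_spec={"a": names[:4], "b": names[4:]},
            target_prevalence={s: 0.6 for s in names},
            intra_cluster_pcor=0.25,
            bridge_edges=[("v0", "v5", 0.2), ("v2", "v7", -0.15)],
        )
        omega, pcor = build_true_network(cfg)
        # oracle: correlation matrix of the implied covariance, inverted
        sigma = np.linalg.inv(omega)
        d = np.sqrt(np.diag(sigma))
        corr = sigma / np.outer(d, d)
        prec = np.linalg.inv(corr)
        dd = np.sqrt(np.diag(prec))
        oracle = -prec / np.outer(dd, dd)
        np.fill_diagonal(oracle, 0.0)
        np.testing.assert_allclose(pcor, oracle, atol=1e-10)

    def test_unrealizable_pcors_name_offending_edges(self):
        names = [f"v{i}" for i in range(5)]
        cfg = GeneratorConfig(
            n_participants=10,
            cluster_spec={"a": names},
            target_prevalence={s: 0.5 for s in names},
            intra_cluster_pcor=0.9,
        )
        with pytest.raises(NotPositiveDefiniteError) as exc:
            build_true_network(cfg)
        assert exc.value.offending_edges

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            GeneratorConfig(
                n_participants=5,
                cluster_spec={"a": ["x", "y"], "b": ["x"]},  # duplicate symptom
                target_prevalence={"x": 0.5, "y": 0.5},
            )
        with pytest.raises(ValidationError):
            GeneratorConfig(
                n_participants=5,
                cluster_spec={"a": ["x", "y"]},
                target_prevalence={"x": 1.5, "y": 0.5},
            )


class TestSampleDataset:
    def test_same_seed_bit_identical(self):
        a = sample_dataset(two_cluster_config(seed=11))
        b = sample_dataset(two_cluster_config(seed=11))
        assert a.severities.equals(b.severities)
        assert a.covariates.equals(b.covariates)

    def test_zero_prevalence_column_all_zero(self):
        cfg = two_cluster_config()
        cfg.target_prevalence["s3"] = 0.0
        ds = sample_dataset(cfg)
        assert (ds.severities["s3"] == 0).all()

    def test_full_prevalence_column_never_zero(self):
        cfg = two_cluster_config()
        cfg.target_prevalence["s3"] = 1.0
        ds = sample_dataset(cfg)
        assert (ds.severities["s3"] >= 1).all()

    def test_severities_within_range(self):
        ds = sample_dataset(two_cluster_config(n=500))
        v = ds.severities.to_numpy()
        assert v.min() >= 0 and v.max() <= 10

    def test_observed_prevalence_within_binomial_bounds(self):
        cfg = two_cluster_config(seed=5, n=5000, prevalence=0.5)
        ds = sample_dataset(cfg)
        lo, hi = binom.ppf([0.005, 0.995], 5000, 0.5)
        counts = (ds.severities > 0).sum()
        assert ((counts >= lo) & (counts <= hi)).all()

    def test_covariate_shift_raises_group_mean(self):
        cfg = two_cluster_config(seed=9, n=5000)
        cfg.covariate_prevalence = {"grp": 0.5}
        cfg.covariate_effects = {"grp": {"s1": 1.0}}
        ds = sample_dataset(cfg)
        g = ds.covariates["grp"].to_numpy()
        sev = ds.severities["s1"].to_numpy()
        assert sev[g == 1].mean() > sev[g == 0].mean()


class TestStudyLikeConfig:
    def test_symptom_names_match_instrument(self):
        cfg = study_like_config()
        assert sorted(cfg.symptom_names) == sorted(reference.SYMPTOM_NAMES)
        assert len(cfg.symptom_names) == 19

    def test_rare_symptoms_below_filter(self):
        cfg = study_like_config()
        assert cfg.target_prevalence["drowsiness"] < 0.20
        assert cfg.target_prevalence["cough with blood"] < 0.20

    def test_same_seed_identical_configs(self):
        assert study_like_config(seed=4) == study_like_config(seed=4)

    def test_json_roundtrip(self, tmp_path):
        cfg = study_like_config(seed=2)
        cfg.to_json(tmp_path / "cfg.json")
        assert GeneratorConfig.from_json(tmp_path / "cfg.json") == cfg


class TestSeverityCuts:
    from hypothesis import given, settings, strategies as st

    @given(
        prevalence=st.floats(min_value=0.0, max_value=1.0),
        severity_max=st.integers(min_value=1, max_value=10),
        z=st.floats(min_value=-6, max_value=6),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_cut_points_monotone_and_severity_in_range(self, prevalence, severity_max, z):
        from sympnet.generate import _severity_cuts

        cuts = _severity_cuts(prevalence, severity_max)
        assert len(cuts) == severity_max
        finite = cuts[np.isfinite(cuts)]
        assert np.all(np.diff(finite) >= 0)
        sev = np.searchsorted(cuts, z, side="right")
        assert 0 <= sev <= severity_max
        if prevalence == 0.0:
            assert sev == 0


class TestLatentModelAgreement:
    """Large-sample severities reproduce the latent model's rank correlations."""

    def test_spearman_matches_independent_latent_oracle(self):
        cfg = two_cluster_config(seed=21, n=20_000, pcor=0.3,
                                 bridges=[("s1", "s4", 0.25)])
        ds = sample_dataset(cfg)
        obs = spearmanr(ds.severities.to_numpy()).statistic

        # oracle: fresh latent normals + quantile thresholds, coded separately
        omega, _ = build_true_network(cfg)
        sigma = np.linalg.inv(omega)
        d = np.sqrt(np.diag(sigma))
        corr = sigma / np.outer(d, d)
        rng = np.random.default_rng(987)
        z = rng.multivariate_normal(np.zeros(6), corr, size=20_000)
        sev = np.zeros_like(z, dtype=int)
        for j, s in enumerate(cfg.symptom_names):
            prev = cfg.target_prevalence[s]
            cuts = norm.ppf(1 - prev + prev * np.arange(10) / 10)
            sev[:, j] = np.searchsorted(cuts, z[:, j], side="right")
        exp = spearmanr(sev).statistic
        assert np.abs(obs - exp).max() < 0.05

    def test_planted_zero_partial_correlations_stay_small(self):
        cfg = two_cluster_config(seed=22, n=20_000, pcor=0.3)
        ds = sample_dataset(cfg)
        R = spearmanr(ds.severities.to_numpy()).statistic
        prec = np.linalg.inv(R)
        dd = np.sqrt(np.diag(prec))
        pcor = -prec / np.outer(dd, dd)
        _, true_pcor = build_true_network(cfg)
        zero_mask = np.triu(true_pcor == 0, 1)
        assert np.abs(pcor[zero_mask]).max() < 0.05
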