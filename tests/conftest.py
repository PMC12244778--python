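import numpy as np
import pandas as pd
import pytest

from sympnet import (
    GeneratorConfig,
    SymptomDataset,
    filter_by_prevalence,
    sample_dataset,
    study_like_config,
)
from sympnet import reference


def two_cluster_config(seed=0, n=150, pcor=0.3, bridges=(), prevalence=0.7):
    """Small 6-symptom, 2-cluster generator used throughout the suite."""
    return GeneratorConfig(
        n_participants=n,
        cluster_spec={"c1": ["s1", "s2", "s3"], "c2": ["s4", "s5", "s6"]},
        target_prevalence={f"s{i}": prevalence for i in range(1, 7)},
        intra_cluster_pcor=pcor,
        bridge_edges=list(bridges),
        seed=seed,
    )


@pytest.fixture(scope="session")
def study_ds():
    """One study-like synthetic cohort (n = 249, 19 symptoms, 3 covariates)."""
    return sample_dataset(study_like_config(seed=0))


@pytest.fixture(scope="session")
def filtered_ds(study_ds):
    ds, _ = filter_by_prevalence(study_ds)
    return ds


@pytest.fixture(scope="session")
def reference_counts_ds():
    """Dataset whose per-symptom occurrence counts equal the published table.

    Participant i has a nonzero score on symptom s iff i < count(s), with the
    nonzero rows rotated per symptom so the columns are not degenerate copies
    of one another.  Only prevalence is calibrated; severities are arbitrary
    small positive integers.
    """
    n = reference.N_ANALYZED
    rng = np.random.default_rng(12345)
    cols = {}
    for k, (name, (count, _, _)) in enumerate(reference.SYMPTOM_SUMMARY.items()):
        col = np.zeros(n, dtype=int)
        present = (np.arange(count) + 13 * k) % n
        col[present] = rng.integers(1, 6, size=count)
        cols[name] = col
    return SymptomDataset(pd.DataFrame(cols))
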