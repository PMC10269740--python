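import numpy as np
import pandas as pd
import pytest

from crcmb.core_io import FeatureTable, SampleMetadata
from crcmb import synthetic_cohort as sc


@pytest.fixture
def tiny_table():
    return FeatureTable(
        ("sA", "sB"), ("f1", "f2", "f3"), np.array([[5, 0, 3], [1, 2, 4]])
    )


def make_metadata(n_subjects, with_covariates=True, survival=None, rng=None):
    """Paired metadata for n_subjects (two samples each)."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for i in range(n_subjects):
        subj = f"S{i + 1:03d}"
        surv = survival[i] if survival is not None else ("short" if i % 2 == 0 else "long")
        for tissue in ("normal", "tumor"):
            row = {
                "sample_id": f"{subj}.{tissue[0].upper()}",
                "subject_id": subj,
                "tissue": tissue,
                "survival": surv,
            }
            if with_covariates:
                row["location"] = ["colon right", "colon left", "rectum"][i % 3]
                row["age"] = ["<60", "60-69", "70-74", ">=75"][i % 4]
            rows.append(row)
    return SampleMetadata(pd.DataFrame(rows))


@pytest.fixture
def paired_metadata():
    return make_metadata(4)


@pytest.fixture(scope="session")
def medium_cohort():
    """A 30-subject, 80-feature cohort with tissue + interaction effects."""
    truth = sc.default_truth(
        80, seed=42, n_tissue_features=12, n_interaction_features=15
    )
    bundle, truth = sc.generate_cohort(30, 15, truth=truth)
    return bundle, truth


@pytest.fixture(scope="session")
def null_cohort():
    """No effects at all, subject_sd=0: fully exchangeable samples."""
    nf = 40
    truth = sc.SyntheticTruth(
        baseline_log_abundance=np.random.default_rng(9).normal(0, 1.0, nf),
        subject_sd=0.0,
        tissue_effect=np.zeros(nf),
        interaction_effect=np.zeros(nf),
        nb_dispersion=0.5,
        depth_log_mean=np.log(20000),
        depth_log_sd=0.5,
        seed=9,
    )
    bundle, truth = sc.generate_cohort(16, 8, truth=truth)
    return bundle, truth
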