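"""Shared fixtures: tiny on-disk inputs and small simulated studies."""

import numpy as np
import pandas as pd
import pytest

from demandomics.io import IntensityMatrix, SampleManifest


@pytest.fixture
def manifest_csv(tmp_path):
    p = tmp_path / "manifest.csv"
    p.write_text(
        "sample_id,subject_id,species,sex,treatment,body_weight_g\n"
        "s1,m1,mouse,male,saline,27.0\n"
        "s2,f1,mouse,female,cocaine,22.5\n"
    )
    return p


@pytest.fixture
def small_matrix():
    """4 proteins x 4 samples with one missing cell and one true zero."""
    df = pd.DataFrame(
        {
            "a1": [1e6, 2e5, 3e4, 1e3],
            "a2": [1.2e6, np.nan, 2.8e4, 1.1e3],
            "b1": [1e5, 2.2e5, 0.0, 0.9e3],
            "b2": [0.9e5, 1.9e5, 3.1e4, 1.2e3],
        },
        index=pd.Index(["p1", "p2", "p3", "p4"], name="accession"),
    )
    return IntensityMatrix(df)


def make_matrix(values: np.ndarray, sample_ids=None, accessions=None) -> IntensityMatrix:
    """Build an IntensityMatrix from a raw (protein x sample) array."""
    n, m = values.shape
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(m)]
    accessions = accessions or [f"p{i + 1}" for i in range(n)]
    return IntensityMatrix(
        pd.DataFrame(values, index=pd.Index(accessions, name="accession"), columns=sample_ids)
    )


def make_manifest(sample_ids, sexes, treatments) -> SampleManifest:
    return SampleManifest(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "subject_id": [f"subj_{s}" for s in sample_ids],
                "species": "mouse",
                "sex": sexes,
                "treatment": treatments,
                "body_weight_g": 25.0,
            }
        )
    )
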