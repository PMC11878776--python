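"""Shared fixtures: a session-scoped synthetic cohort and its features.

The cohort is generated once at the package defaults (4 classes x 10 slides,
4096-px slides, 0.549 um/px) and feature-extracted once; the end-to-end
cross-validation and ablation tests all reuse it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hiwsi.pipeline import extract_features
from hiwsi.synthetic import SyntheticCohortSpec, generate_cohort
from hiwsi.tiling import read_manifest

COHORT_SEED = 7


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    spec = SyntheticCohortSpec(seed=COHORT_SEED)
    generate_cohort(spec, out)
    return out


@pytest.fixture(scope="session")
def cohort_manifest(cohort_dir) -> pd.DataFrame:
    return pd.read_csv(cohort_dir / "manifest.csv")


@pytest.fixture(scope="session")
def cohort_records(cohort_dir):
    return read_manifest(cohort_dir / "manifest.csv")


@pytest.fixture(scope="session")
def cohort_features(cohort_records):
    return extract_features(cohort_records)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
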