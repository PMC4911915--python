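"""Shared fixtures: one small synthetic study reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from selhier.features import TranscriptFeatures
from selhier.models import RateParameters, SeMap
from selhier.synthetic import make_gene_panel, simulate_dataset

try:
    from hypothesis import settings

    settings.register_profile("ci", max_examples=25, deadline=None, derandomize=True)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def features() -> TranscriptFeatures:
    return TranscriptFeatures("GENE", 120, 60, 80)


@pytest.fixture(scope="session")
def params() -> RateParameters:
    return RateParameters()


@pytest.fixture(scope="session")
def se_map() -> SeMap:
    return SeMap()


@pytest.fixture(scope="session")
def panel_truth():
    """Default 11-gene panel with ground truth (seed fixed for the session)."""
    return make_gene_panel(seed=1)


@pytest.fixture(scope="session")
def dataset(panel_truth):
    _, truth = panel_truth
    return simulate_dataset(truth, seed=2)


@pytest.fixture(scope="session")
def features_by_gene(panel_truth):
    panel, _ = panel_truth
    return {f.gene_id: f for f in panel}


def random_positive_params(rng: np.random.Generator, with_drop: bool = False) -> RateParameters:
    """Log-uniform draw of a generic positive parameter set (test helper)."""
    return RateParameters(
        v_txn=10 ** rng.uniform(-0.5, 1.0),
        k_init=10 ** rng.uniform(-0.5, 1.5),
        r_elong=10 ** rng.uniform(3.0, 4.2),
        k_bind=10 ** rng.uniform(-1.0, 2.0),
        k_nmd=10 ** rng.uniform(-2.0, 1.0),
        k_sec=10 ** rng.uniform(-0.5, 1.5),
        k_drop=10 ** rng.uniform(-1.0, 1.5) if with_drop else 0.0,
        d_bg=10 ** rng.uniform(-2.0, 0.0),
    )


def random_features(rng: np.random.Generator, gene_id: str = "G") -> TranscriptFeatures:
    return TranscriptFeatures(
        gene_id,
        int(rng.integers(40, 400)),
        int(rng.integers(10, 300)),
        int(rng.integers(0, 200)),
    )
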