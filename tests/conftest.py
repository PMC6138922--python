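"""Shared fixtures: small synthetic communities and estimators.

All randomness is seeded; hypothesis runs derandomised so the suite is
bit-reproducible.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from binforge.quality import (
    annotate_markers,
    make_gold_estimator,
    make_marker_estimator,
)
from binforge.synth import corrupt_binning, make_community

settings.register_profile(
    "fast",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fast")


@pytest.fixture(scope="session")
def community():
    """Small mixed community: 4 unique genomes + 1 strain pair."""
    return make_community(
        n_unique=4,
        n_common_pairs=1,
        genome_length=20_000,
        n_markers=30,
        marker_length=40,
        contig_median=4_000,
        min_contig=800,
        seed=7,
    )


@pytest.fixture(scope="session")
def marker_profile(community):
    return annotate_markers(community.assembly.sequences, community.catalog)


@pytest.fixture(scope="session")
def marker_estimator(community, marker_profile):
    return make_marker_estimator(marker_profile, community.catalog, community.lengths)


@pytest.fixture(scope="session")
def gold_estimator(community):
    return make_gold_estimator(community.gold, community.lengths)


@pytest.fixture()
def corrupted_binnings(community):
    """Three differently-corrupted binnings of the community."""
    rng = np.random.default_rng(21)
    return [
        corrupt_binning(
            community.gold,
            dropout=rng.uniform(0.2, 0.4),
            misassignment=rng.uniform(0.05, 0.15),
            n_merges=1,
            n_splits=1,
            rng=rng,
            label=f"binner{i + 1}",
        )
        for i in range(3)
    ]
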