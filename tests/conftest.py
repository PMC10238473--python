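"""Shared fixtures: one small and one default-size synthetic dataset per
session, plus segmentation-derived spot pools."""

from __future__ import annotations

import numpy as np
import pytest

from stpower.config import SimConfig
from stpower.discovery import kuppe_score, normalize_counts, segment_spots
from stpower.geomx import restrict_to_class
from stpower.synth import generate_bulk_cohort, generate_spot_dataset


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=101, n_samples=3, grid_rows=24, grid_cols=24,
                     n_genes=300, marker_fold=6.0)


@pytest.fixture(scope="session")
def small_spots(small_config):
    return generate_spot_dataset(small_config)


@pytest.fixture(scope="session")
def small_bulk(small_config):
    return generate_bulk_cohort(small_config)


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def default_spots(default_config):
    return generate_spot_dataset(default_config)


def segment_with_scores(spots, config):
    """Normalize, score and segment a spot dataset with its marker sets."""
    sets = config.resolved_marker_sets()
    norm = normalize_counts(
        spots.counts, genes=spots.genes, columns=spots.spot_meta.index,
        size_factor_method="poscounts",
    )
    hep = kuppe_score(norm, sets["hepatocyte"], name="hepatocyte")
    ecm = kuppe_score(norm, sets["ecm"], name="ecm")
    return segment_spots(spots, hep, ecm)


@pytest.fixture(scope="session")
def default_segmentation(default_spots, default_config):
    return segment_with_scores(default_spots, default_config)


@pytest.fixture(scope="session")
def hepatocyte_pool(default_spots, default_segmentation):
    return restrict_to_class(default_spots, default_segmentation, "hepatocyte")


@pytest.fixture(scope="session")
def niche_pool(default_spots, default_segmentation):
    return restrict_to_class(default_spots, default_segmentation, "niche")


@pytest.fixture(scope="session")
def small_segmentation(small_spots, small_config):
    return segment_with_scores(small_spots, small_config)
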