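"""Shared fixtures: tiny hand-written tables and small generator scenarios."""

from __future__ import annotations

import numpy as np
import pytest

from aerotransfer import (
    ContaminantSpec,
    EnvironmentSpec,
    FeatureTable,
    LivestockLink,
    Metadata,
    SampleRecord,
    SyntheticScenario,
    TaxonomyTable,
)


@pytest.fixture
def tiny_table() -> FeatureTable:
    """3 features x 2 samples with column sums (6, 9)."""
    return FeatureTable(
        np.array([[5, 0], [1, 2], [0, 7]]), ["f1", "f2", "f3"], ["s1", "s2"]
    )


@pytest.fixture
def tiny_metadata() -> Metadata:
    return Metadata(
        [
            SampleRecord("s1", "cow_home", season="summer", farm_id="farmA"),
            SampleRecord("s2", "cow_stable", season="summer", farm_id="farmA"),
        ]
    )


@pytest.fixture
def tiny_taxonomy() -> TaxonomyTable:
    return TaxonomyTable(
        {
            "f1": ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
                   "Lactobacillaceae", "Lactobacillus", ""),
            "f2": ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
                   "Lactobacillaceae", "Lactobacillus", ""),
            "f3": ("Bacteria", "Firmicutes", "Clostridia", "Lachnospirales",
                   "Lachnospiraceae", "", ""),
        }
    )


def small_paired_scenario(
    seed: int,
    n_farms: int = 10,
    tau: float = 0.0,
    n_features: int = 150,
    depth: float = 2000.0,
    sigma: float = 0.6,
    home_sigma: float | None = None,
    depth_cv: float = 0.0,
    divergence: float = 0.5,
    n_controls: int = 0,
) -> SyntheticScenario:
    """A cow home/stable cohort small enough for replicated simulation tests."""
    return SyntheticScenario(
        n_features=n_features,
        environments=[
            EnvironmentSpec(
                "cow_home", n_farms, sigma=sigma if home_sigma is None else home_sigma
            ),
            EnvironmentSpec("cow_stable", n_farms, sigma=sigma),
        ],
        links=[LivestockLink("cow", n_farms, tau=tau)],
        n_controls=n_controls,
        divergence=divergence,
        depth_mean=depth,
        depth_cv=depth_cv,
        contaminants=ContaminantSpec(
            n_features=5, prevalence_in_controls=0.9, prevalence_in_samples=0.0
        ),
        seed=seed,
    )
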