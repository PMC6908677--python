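"""Shared fixtures: one planted synthetic genome, simulated and balanced
contact maps for every condition, and the derived compartment tracks.
Session scope keeps the suite fast — the maps are simulated once."""

import numpy as np
import pytest

from senhic import (
    SyntheticConfig,
    ice_normalize,
    pca_scores,
    plant_architecture,
    simulate_contacts,
    simulate_expression_and_tracks,
)

CONDITIONS = ("growing", "senescent", "kd")


@pytest.fixture(scope="session")
def syn_config():
    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def truth(syn_config):
    return plant_architecture(syn_config)


@pytest.fixture(scope="session")
def genes_tracks(truth):
    return simulate_expression_and_tracks(truth)


@pytest.fixture(scope="session")
def iced_all(truth):
    """ICE-balanced maps for every (condition, chromosome)."""
    return {
        (cond, chrom): ice_normalize(simulate_contacts(truth, cond, chrom))
        for cond in CONDITIONS
        for chrom in truth.chroms()
    }


@pytest.fixture(scope="session")
def pca_all(iced_all, genes_tracks):
    _, tracks = genes_tracks
    return {
        key: pca_scores(m, tracks["gene_density"][key[1]])
        for key, m in iced_all.items()
    }


@pytest.fixture(scope="session")
def iced_chr1(iced_all):
    return {cond: iced_all[(cond, "chr1")] for cond in CONDITIONS}


@pytest.fixture(scope="session")
def iced_senescent(iced_all, truth):
    return {chrom: iced_all[("senescent", chrom)] for chrom in truth.chroms()}


@pytest.fixture(scope="session")
def pca_chr1(pca_all):
    return {cond: pca_all[(cond, "chr1")] for cond in CONDITIONS}


@pytest.fixture(scope="session")
def pca_senescent(pca_all, truth):
    return {chrom: pca_all[("senescent", chrom)] for chrom in truth.chroms()}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
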