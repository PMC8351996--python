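"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from ldrepulsion import (
    DemographyModel,
    DFEModel,
    HaplotypeSample,
    SimulationConfig,
    simulate,
)


def make_sample(haplotypes, positions, annotations, s=None) -> HaplotypeSample:
    """Hand-build a HaplotypeSample from a 2n x m 0/1 array."""
    H = np.asarray(haplotypes, dtype=np.uint8)
    m = H.shape[1]
    sites = pd.DataFrame(
        {
            "position": np.asarray(positions, dtype=np.int64),
            "annotation": list(annotations),
            "s": np.zeros(m) if s is None else np.asarray(s, dtype=float),
            "h": np.full(m, 0.5),
            "origin_generation": np.zeros(m, dtype=np.int32),
        }
    )
    return HaplotypeSample(haplotypes=H, sites=sites)


def doubleton_sample(n_chrom=100, pos=(100, 2100), coupled=True, annotation="NS"):
    """Two doubleton sites: derived alleles on the same two chromosomes
    (coupled) or on four distinct chromosomes (complete repulsion)."""
    H = np.zeros((n_chrom, 2), dtype=np.uint8)
    H[0, 0] = H[1, 0] = 1
    if coupled:
        H[0, 1] = H[1, 1] = 1
    else:
        H[2, 1] = H[3, 1] = 1
    return make_sample(H, pos, [annotation, annotation])


@pytest.fixture(scope="session")
def small_dfe_sample() -> HaplotypeSample:
    """One scaled Model 1 replicate with the gamma DFE (~2 s)."""
    cfg = SimulationConfig(
        length=500_000,
        r=1e-8,
        rescale_factor=20,
        seed=11,
        demography=DemographyModel.model1(),
        dfe=DFEModel(),
        track_noncoding=False,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_neutral_sample() -> HaplotypeSample:
    """One scaled neutral Model 1 replicate including noncoding sites."""
    cfg = SimulationConfig(
        length=300_000,
        r=1e-8,
        rescale_factor=20,
        seed=13,
        demography=DemographyModel.model1(),
        dfe=DFEModel.neutral(),
        track_noncoding=True,
    )
    return simulate(cfg)
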