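"""Shared fixtures: small simulated crosses reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from ailgxe import haplotypes, simdata


@pytest.fixture(scope="session")
def small_panel():
    """4 founders, 2 chromosomes x 25 markers over 100 cM, all informative."""
    return simdata.simulate_founders(
        4, {"chr1": (25, 100.0), "chr2": (25, 100.0)}, fraction_private=1.0, seed=11
    )


@pytest.fixture(scope="session")
def small_cross(small_panel):
    cfg = simdata.SimConfig(
        generations=10, breeding_pairs=30, n_offspring=5, genotyping_error=0.002, seed=12
    )
    ped, diplo, gm = simdata.simulate_cross(small_panel, cfg)
    return ped, diplo, gm


@pytest.fixture(scope="session")
def small_posterior(small_cross):
    _, _, gm = small_cross
    gq, _ = haplotypes.qc_filter(gm)
    return haplotypes.reconstruct(gq, generations=10, eps=0.002)


@pytest.fixture(scope="session")
def small_kinship(small_posterior):
    return haplotypes.kinship(small_posterior)


def make_marker_df(n, chrom="chr1", spacing_cm=2.0):
    cm = np.arange(n) * spacing_cm
    return pd.DataFrame(
        {"chrom": chrom, "bp": (cm * 2e6).astype(int) + 1, "cM": cm}
    )
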