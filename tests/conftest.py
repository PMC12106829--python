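"""Shared fixtures: small genotype builders and one session-scoped panel."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tefpop.genotypes import GenotypeMatrix
from tefpop.synthetic import PanelConfig, call_genotypes, generate_panel


def make_geno(calls, samples=None, chrom="chr1", positions=None,
              ref="A", alt="G") -> GenotypeMatrix:
    """GenotypeMatrix from a (sites x samples) list of call codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n_sites, n_samples = calls.shape
    samples = samples or [f"s{i + 1}" for i in range(n_samples)]
    positions = positions or list(range(100, 100 + 10 * n_sites, 10))
    sites = pd.DataFrame({
        "chrom": [chrom] * n_sites, "pos": positions,
        "ref": [ref] * n_sites, "alt": [alt] * n_sites})
    return GenotypeMatrix(samples, sites, calls)


@pytest.fixture(scope="session")
def panel40():
    """Default 40-accession panel with planted groups, mixture,
    introgression and one swept causal locus."""
    from tefpop.pipeline import default_panel_config

    return generate_panel(default_panel_config(seed=11))


@pytest.fixture(scope="session")
def geno40(panel40):
    return call_genotypes(panel40, missing_rate=0.02, seed=111)


@pytest.fixture(scope="session")
def kmer_sets40(panel40):
    from tefpop import kmers

    return {acc: kmers.kmer_array(panel40.sequences(acc), 51)
            for acc in panel40.accessions}


@pytest.fixture(scope="session")
def kmat40(kmer_sets40):
    from tefpop import kmers

    return kmers.build_kmer_matrix(kmer_sets40, min_presence=2, k=51)
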