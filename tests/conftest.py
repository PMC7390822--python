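"""Shared fixtures: packaged reference peptide-pair data and small helpers."""

from importlib import resources

import pytest

from neoclone.binding import load_table1_affinities
from neoclone.peptides import read_protein_fasta, read_variant_table


@pytest.fixture(scope="session")
def table1_contexts():
    """Wild-type local contexts of the six published mutations, keyed by gene."""
    path = resources.files("neoclone.data") / "table1_contexts.fasta"
    return {rec.gene: rec for rec in read_protein_fasta(path)}


@pytest.fixture(scope="session")
def table1_variants():
    """The six published variants (synthetic VAFs), keyed by gene."""
    path = resources.files("neoclone.data") / "table1_variants_synthetic_vaf.tsv"
    return {v.gene: v for v in read_variant_table(path)}


@pytest.fixture(scope="session")
def table1_affinities():
    """Transcription of the 13 published peptide pairs with predicted IC50s."""
    return load_table1_affinities()
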