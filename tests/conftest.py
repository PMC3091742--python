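"""Shared fixtures: synthetic genomes and derived reference sets."""

import numpy as np
import pytest

from mitocomp.genome_io import extract_gene_seq
from mitocomp.synthetic_data import GenomeSimConfig, generate_mitogenome
from mitocomp.trna_struct import ReferenceTrnaSet


@pytest.fixture(scope="session")
def synthetic_genome():
    """One default mite-like synthetic genome (seed 1) with its manifest."""
    return generate_mitogenome(GenomeSimConfig(seed=1))


@pytest.fixture(scope="session")
def synthetic_record(synthetic_genome):
    return synthetic_genome[0]


@pytest.fixture(scope="session")
def synthetic_manifest(synthetic_genome):
    return synthetic_genome[1]


def mutated_reference_set(record, divergence: float = 0.10, seed: int = 0):
    """Reference tRNAs for a record: its planted tRNA sequences mutated to
    the given divergence (emulating homologs from a related taxon)."""
    rng = np.random.default_rng(seed)
    refs = {}
    for f in record.features:
        if f.kind != "tRNA":
            continue
        s = extract_gene_seq(record, f)
        refs[f.name] = "".join(
            c if rng.random() > divergence
            else str(rng.choice([b for b in "ACGT" if b != c]))
            for c in s
        )
    return ReferenceTrnaSet(refs)


def trna_truth(record):
    """(strand, begin, end) per planted isoacceptor."""
    return {
        f.name: (f.strand, f.begin, f.end)
        for f in record.features
        if f.kind == "tRNA"
    }
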