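import numpy as np
import pytest

from comphet.seqio import DNA, PROTEIN, Alignment


@pytest.fixture
def rng():
    return np.random.default_rng(20240615)


def make_dna_alignment(taxa_rows: dict[str, str], charsets=None) -> Alignment:
    taxa = list(taxa_rows)
    matrix = np.array([list(s) for s in taxa_rows.values()], dtype="<U1")
    return Alignment(taxa=taxa, matrix=matrix, alphabet=DNA, charsets=charsets or {})


def make_aa_alignment(taxa_rows: dict[str, str]) -> Alignment:
    taxa = list(taxa_rows)
    matrix = np.array([list(s) for s in taxa_rows.values()], dtype="<U1")
    return Alignment(taxa=taxa, matrix=matrix, alphabet=PROTEIN)


def random_dna_alignment(rng, n_taxa=4, n_sites=60, with_ambiguity=False):
    codes = list("ACGT") + (["-", "?", "N", "R", "Y"] if with_ambiguity else [])
    p = None
    if with_ambiguity:
        p = np.array([0.22, 0.22, 0.22, 0.22, 0.03, 0.03, 0.02, 0.02, 0.02])
    matrix = rng.choice(codes, size=(n_taxa, n_sites), p=p)
    return Alignment(
        taxa=[f"t{i}" for i in range(n_taxa)], matrix=matrix, alphabet=DNA
    )
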