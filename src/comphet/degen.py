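"""Codon-degenerate recoding: removing synonymous substitutions in place.

Each codon is replaced by an IUPAC-ambiguity triplet that covers every
codon of its synonymous family, so that two sequences differing only by
within-family synonymous change become identical after recoding and only
non-synonymous differences remain.

The degen-1 convention is used: the sixfold leucine and arginine
families are merged (Leu -> YTN, Arg -> MGN), serine stays as two
families (TCN and AGY) because its two codon groups are not connected by
single-position synonymous change, and the stop codons form the groups
TAR and TGA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from typing import Mapping

import numpy as np
from Bio.Data import CodonTable
from Bio.Data.IUPACData import ambiguous_dna_values

from .seqio import Alignment, AlignmentError

logger = logging.getLogger(__name__)

__all__ = ["DegenTable", "build_degen_table", "degen_recode"]

# state-set -> IUPAC code (inverse of the expansion map)
_IUPAC_OF: dict[frozenset, str] = {
    frozenset(v): k for k, v in ambiguous_dna_values.items() if k != "X"
}


def iupac_cover(states) -> str:
    """Smallest IUPAC code whose expansion is exactly the given state set."""
    return _IUPAC_OF[frozenset(states)]


@dataclass(frozen=True)
class DegenTable:
    """64-codon map to degenerate triplets plus family membership."""

    code_table_id: int
    mapping: Mapping[str, str]  # codon -> degenerate triplet
    family_index: Mapping[str, int]  # codon -> degeneracy group id
    families: tuple[tuple[str, ...], ...]  # group id -> member codons

    def degenerate(self, codon: str) -> str:
        return self.mapping[codon]


def _codon_families(code_table_id: int) -> list[list[str]]:
    table = CodonTable.unambiguous_dna_by_id[code_table_id]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    families: list[list[str]] = []
    for aa, codons in sorted(by_aa.items()):
        if aa == "S":
            # two serine families: TCN and AGY are not single-step synonyms
            families.append(sorted(c for c in codons if c.startswith("TC")))
            families.append(sorted(c for c in codons if c.startswith("AG")))
        else:
            families.append(sorted(codons))
    # stop codons: TAA/TAG share third-position degeneracy; TGA stands alone
    stops = sorted(table.stop_codons)
    tar = [c for c in stops if c in ("TAA", "TAG")]
    rest = [c for c in stops if c not in ("TAA", "TAG")]
    if tar:
        families.append(tar)
    for c in rest:
        families.append([c])
    return families


def build_degen_table(code_table_id: int = 1) -> DegenTable:
    """Construct the degen-1 recoding table for a genetic code.

    The degenerate triplet of a family is the positionwise IUPAC cover
    of its member codons, so e.g. the fourfold glycine family
    {GGA,GGC,GGG,GGT} maps to GGN, and the merged leucine family
    {TTA,TTG,CTA,CTC,CTG,CTT} maps to YTN.
    """
    try:
        CodonTable.unambiguous_dna_by_id[code_table_id]
    except KeyError:
        raise ValueError(f"unknown genetic code table {code_table_id}")
    families = _codon_families(code_table_id)
    mapping: dict[str, str] = {}
    family_index: dict[str, int] = {}
    for gid, fam in enumerate(families):
        triplet = "".join(
            iupac_cover({codon[pos] for codon in fam}) for pos in range(3)
        )
        for codon in fam:
            mapping[codon] = triplet
            family_index[codon] = gid
    assert len(mapping) == 64
    return DegenTable(
        code_table_id=code_table_id,
        mapping=mapping,
        family_index=family_index,
        families=tuple(tuple(f) for f in families),
    )


def _recode_codon(codon: str, t: DegenTable, alphabet) -> str:
    """Union-cover recoding of one codon (may contain partial ambiguity)."""
    for c in codon:
        if alphabet.is_missing_for_counting(c):
            return codon  # pass through untouched
    state_sets = [sorted(alphabet.code_states(c)) for c in codon]
    cover = [set(), set(), set()]
    for combo in product(*state_sets):
        deg = t.mapping["".join(combo)]
        for pos in range(3):
            cover[pos] |= set(ambiguous_dna_values[deg[pos]])
    return "".join(iupac_cover(cover[pos]) for pos in range(3))


def degen_recode(
    a: Alignment, t: DegenTable | None = None, with_stats: bool = False
):
    """Degenerate-recode an in-frame nucleotide alignment.

    Complete unambiguous codons are replaced by their family's
    degenerate triplet.  Codons containing a gap or missing code are
    copied through unchanged.  Input ambiguity codes are recoded
    positionwise to the union cover of all compatible codons' degenerate
    triplets.

    With ``with_stats=True`` returns ``(alignment, stats)`` where stats
    counts recoded and passed-through codons.
    """
    if a.alphabet.kind != "nucleotide":
        raise AlignmentError("degenerate recoding requires nucleotide data")
    if a.n_sites % 3 != 0 or not a.frame_ok:
        raise AlignmentError("alignment is not in frame")
    if t is None:
        t = build_degen_table(1)

    cache: dict[str, str] = {}
    n_recoded = 0
    n_passed = 0
    out = a.matrix.copy()
    n_codons = a.n_sites // 3
    for ti in range(a.n_taxa):
        row = a.matrix[ti]
        for ci in range(n_codons):
            codon = "".join(row[3 * ci : 3 * ci + 3])
            if codon not in cache:
                cache[codon] = _recode_codon(codon, t, a.alphabet)
            recoded = cache[codon]
            if recoded == codon and any(
                a.alphabet.is_missing_for_counting(c) for c in codon
            ):
                n_passed += 1
            else:
                n_recoded += 1
            out[ti, 3 * ci : 3 * ci + 3] = list(recoded)

    result = Alignment(
        taxa=list(a.taxa),
        matrix=out,
        alphabet=a.alphabet,
        charsets={k: v.copy() for k, v in a.charsets.items()},
    )
    stats = {"codons_recoded": n_recoded, "codons_passed_through": n_passed}
    logger.info(
        "degen recoding: %d codons recoded, %d passed through",
        n_recoded,
        n_passed,
    )
    if with_stats:
        return result, stats
    return result
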