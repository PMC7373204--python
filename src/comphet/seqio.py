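"""Alignment input/output, concatenation, translation and per-taxon summaries.

The central container is :class:`Alignment`: a taxa-by-sites character
matrix over a :class:`StateAlphabet` (nucleotide or amino acid), together
with named character sets (genes, codon positions).  Coordinates are
0-based half-open internally; NEXUS charsets are converted from the
1-based inclusive convention at the boundary.

Parsing of FASTA/PHYLIP/NEXUS is delegated to Biopython
(:mod:`Bio.AlignIO`, :mod:`Bio.Nexus`).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Data import CodonTable
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Nexus import Nexus
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Align import MultipleSeqAlignment

logger = logging.getLogger(__name__)

__all__ = [
    "StateAlphabet",
    "DNA",
    "PROTEIN",
    "Alignment",
    "TaxonSummary",
    "AlignmentError",
    "read_alignment",
    "write_alignment",
    "concatenate",
    "summarize_taxa",
    "group_missing_stats",
    "translate",
]


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged rows, bad codes, bad frame)."""


# ---------------------------------------------------------------------------
# Alphabets
# ---------------------------------------------------------------------------

_AA_STATES = tuple("ARNDCQEGHILKMFPSTWYV")

_AA_AMBIGUITY = {
    "B": frozenset("ND"),
    "Z": frozenset("QE"),
    "J": frozenset("IL"),
}


@dataclass(frozen=True)
class StateAlphabet:
    """Canonical states plus ambiguity/gap/missing code semantics.

    ``ambiguity_map`` sends every legal code to the subset of canonical
    states it may represent; canonical codes map to singletons, and
    gap/missing codes map to the full state set (they contribute a flat
    indicator in likelihood computations) but are flagged separately for
    counting purposes.
    """

    kind: str  # "nucleotide" | "amino-acid"
    states: tuple[str, ...]
    ambiguity_map: Mapping[str, frozenset]
    gap_codes: frozenset = frozenset("-")
    missing_codes: frozenset = frozenset("?")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def legal(self, code: str) -> bool:
        return (
            code in self.ambiguity_map
            or code in self.gap_codes
            or code in self.missing_codes
        )

    def code_states(self, code: str) -> frozenset:
        """Canonical states compatible with ``code`` (full set for gap/missing)."""
        if code in self.gap_codes or code in self.missing_codes:
            return frozenset(self.states)
        try:
            return self.ambiguity_map[code]
        except KeyError:
            raise AlignmentError(f"illegal character {code!r} for {self.kind} data")

    def is_missing_for_counting(self, code: str) -> bool:
        """Gap, '?', or the fully ambiguous code (N or X)."""
        if code in self.gap_codes or code in self.missing_codes:
            return True
        return len(self.ambiguity_map.get(code, ())) == self.n_states

    def indicator(self, code: str) -> np.ndarray:
        """0/1 vector over canonical states (partial likelihood at a tip)."""
        s = self.code_states(code)
        return np.array([1.0 if x in s else 0.0 for x in self.states])


def _dna_alphabet() -> StateAlphabet:
    amb = {}
    for code, expansion in ambiguous_dna_values.items():
        amb[code] = frozenset(expansion)
    # U treated as T on input normalisation, not listed here
    return StateAlphabet(
        kind="nucleotide",
        states=tuple("ACGT"),
        ambiguity_map=amb,
    )


def _protein_alphabet() -> StateAlphabet:
    amb = {s: frozenset([s]) for s in _AA_STATES}
    amb.update(_AA_AMBIGUITY)
    amb["X"] = frozenset(_AA_STATES)
    return StateAlphabet(
        kind="amino-acid",
        states=_AA_STATES,
        ambiguity_map=amb,
    )


DNA = _dna_alphabet()
PROTEIN = _protein_alphabet()


def alphabet_for(kind: str) -> StateAlphabet:
    if kind in ("nucleotide", "dna", "nt"):
        return DNA
    if kind in ("amino-acid", "protein", "aa"):
        return PROTEIN
    raise ValueError(f"unknown alphabet kind {kind!r}")


# ---------------------------------------------------------------------------
# Alignment container
# ---------------------------------------------------------------------------


@dataclass
class Alignment:
    """Taxa x sites character matrix with named site sets.

    ``charsets`` maps a name to a sorted integer array of 0-based site
    indices.  Gene charsets on nucleotide data are expected to be
    in-frame (length divisible by 3); :attr:`frame_ok` reports this.
    """

    taxa: list[str]
    matrix: np.ndarray  # dtype '<U1', shape (n_taxa, n_sites)
    alphabet: StateAlphabet
    charsets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2:
            raise AlignmentError("matrix must be 2-dimensional")
        if len(self.taxa) != self.matrix.shape[0]:
            raise AlignmentError("taxa list does not match matrix rows")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = {t for t in self.taxa if self.taxa.count(t) > 1}
            raise AlignmentError(f"duplicate taxon names: {sorted(dupes)}")
        self.charsets = {
            k: np.asarray(sorted(v), dtype=int) for k, v in self.charsets.items()
        }
        for name, idx in self.charsets.items():
            if len(idx) and (idx[0] < 0 or idx[-1] >= self.n_sites):
                raise AlignmentError(
                    f"charset {name!r} outside [0, {self.n_sites})"
                )
        self._validate_codes()

    def _validate_codes(self) -> None:
        codes = np.unique(self.matrix)
        for c in codes:
            if not self.alphabet.legal(c):
                taxon_i, site_i = np.argwhere(self.matrix == c)[0]
                raise AlignmentError(
                    f"illegal character {c!r} at taxon "
                    f"{self.taxa[taxon_i]!r}, site {site_i}"
                )

    # -- basic properties ---------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @property
    def frame_ok(self) -> bool:
        """True when every gene charset (and the whole matrix) is in-frame."""
        if self.alphabet.kind != "nucleotide":
            return False
        if self.n_sites % 3 != 0:
            return False
        gene_sets = self.gene_charsets()
        return all(len(v) % 3 == 0 for v in gene_sets.values())

    def gene_charsets(self) -> dict[str, np.ndarray]:
        """Charsets that look like gene spans (not codon-position sets)."""
        return {
            k: v
            for k, v in self.charsets.items()
            if not re.search(r"pos[123]$", k)
        }

    def taxon_index(self, taxon: str) -> int:
        try:
            return self.taxa.index(taxon)
        except ValueError:
            raise KeyError(f"unknown taxon {taxon!r}")

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self.taxon_index(taxon)]

    def sequence(self, taxon: str) -> str:
        return "".join(self.row(taxon))

    def subset_taxa(self, taxa: Sequence[str]) -> "Alignment":
        idx = [self.taxon_index(t) for t in taxa]
        return Alignment(
            taxa=list(taxa),
            matrix=self.matrix[idx].copy(),
            alphabet=self.alphabet,
            charsets={k: v.copy() for k, v in self.charsets.items()},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.alphabet.kind == other.alphabet.kind
            and np.array_equal(self.matrix, other.matrix)
            and self.charsets.keys() == other.charsets.keys()
            and all(
                np.array_equal(self.charsets[k], other.charsets[k])
                for k in self.charsets
            )
        )


@dataclass
class TaxonSummary:
    """Per-taxon composition and missing-data statistics."""

    taxon: str
    n_sites: int
    pct_missing: float
    pct_gc: float | None  # None for amino-acid data or when undefined
    composition: np.ndarray | None  # None when no unambiguous site exists


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------


def _normalise(seq: str, alphabet: StateAlphabet) -> str:
    s = seq.upper().replace(".", "-")
    if alphabet.kind == "nucleotide":
        s = s.replace("U", "T")
    return s


def _from_biopython(records, alphabet: StateAlphabet) -> Alignment:
    taxa = [rec.id for rec in records]
    rows = [list(_normalise(str(rec.seq), alphabet)) for rec in records]
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise AlignmentError(f"ragged alignment: row lengths {sorted(lengths)}")
    return Alignment(taxa=taxa, matrix=np.array(rows, dtype="<U1"), alphabet=alphabet)


def _read_nexus(path: str | Path, alphabet: StateAlphabet) -> Alignment:
    nex = Nexus.Nexus(str(path))
    taxa = list(nex.taxlabels) if nex.taxlabels else list(nex.matrix.keys())
    rows = []
    for t in taxa:
        if t not in nex.matrix:
            raise AlignmentError(f"taxon {t!r} declared but has no sequence")
        rows.append(list(_normalise(str(nex.matrix[t]), alphabet)))
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise AlignmentError(f"ragged alignment: row lengths {sorted(lengths)}")
    charsets = {
        name: np.asarray(sorted(sites), dtype=int)
        for name, sites in nex.charsets.items()
    }
    return Alignment(
        taxa=taxa,
        matrix=np.array(rows, dtype="<U1"),
        alphabet=alphabet,
        charsets=charsets,
    )


def read_alignment(
    path: str | Path, format: str = "fasta", kind: str = "nucleotide"
) -> Alignment:
    """Read an alignment from ``path``.

    Parameters
    ----------
    format : {"fasta", "phylip", "nexus"}
    kind : {"nucleotide", "amino-acid"}
        State alphabet of the data.  NEXUS ``charset`` statements
        (1-based inclusive) are converted to 0-based site index sets.
    """
    alphabet = alphabet_for(kind)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "nexus":
        return _read_nexus(path, alphabet)
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
    elif format == "phylip":
        records = list(AlignIO.read(str(path), "phylip-relaxed"))
    else:
        raise ValueError(f"unsupported format {format!r}")
    if not records:
        raise AlignmentError(f"no sequences in {path}")
    return _from_biopython(records, alphabet)


def _charset_to_nexus_ranges(idx: np.ndarray) -> str:
    """0-based index array -> NEXUS 1-based inclusive range expression."""
    parts = []
    i = 0
    idx = np.asarray(idx)
    while i < len(idx):
        j = i
        while j + 1 < len(idx) and idx[j + 1] == idx[j] + 1:
            j += 1
        if i == j:
            parts.append(f"{idx[i] + 1}")
        else:
            parts.append(f"{idx[i] + 1}-{idx[j] + 1}")
        i = j + 1
    return " ".join(parts)


def write_alignment(a: Alignment, path: str | Path, format: str = "fasta") -> None:
    """Write ``a`` to ``path`` in FASTA, relaxed PHYLIP or NEXUS format.

    NEXUS output includes a SETS block with one ``charset`` line per
    named site set.
    """
    path = Path(path)
    if format == "fasta":
        recs = [
            SeqRecord(Seq(a.sequence(t)), id=t, description="") for t in a.taxa
        ]
        SeqIO.write(recs, str(path), "fasta")
        return
    if format == "phylip":
        msa = MultipleSeqAlignment(
            [SeqRecord(Seq(a.sequence(t)), id=t, description="") for t in a.taxa]
        )
        AlignIO.write(msa, str(path), "phylip-relaxed")
        return
    if format == "nexus":
        datatype = "dna" if a.alphabet.kind == "nucleotide" else "protein"
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nbegin data;\n")
            fh.write(f"    dimensions ntax={a.n_taxa} nchar={a.n_sites};\n")
            fh.write(
                f"    format datatype={datatype} gap=- missing=? interleave=no;\n"
            )
            fh.write("    matrix\n")
            width = max(len(t) for t in a.taxa) + 2
            for t in a.taxa:
                safe = t.replace(" ", "_")
                fh.write(f"    {safe:<{width}}{a.sequence(t)}\n")
            fh.write("    ;\nend;\n")
            if a.charsets:
                fh.write("\nbegin sets;\n")
                for name, idx in a.charsets.items():
                    fh.write(
                        f"    charset {name} = "
                        f"{_charset_to_nexus_ranges(idx)};\n"
                    )
                fh.write("end;\n")
        return
    raise ValueError(f"unsupported format {format!r}")


# ---------------------------------------------------------------------------
# Concatenation
# ---------------------------------------------------------------------------


def concatenate(
    alignments: Sequence[Alignment],
    names: Sequence[str] | None = None,
    fill_missing: str | None = None,
) -> Alignment:
    """Concatenate gene alignments into one supermatrix.

    The taxon set is the union of the inputs' taxa (first-appearance
    order); blocks for genes a taxon lacks are filled with the missing
    code.  Each input's span is recorded as a gene charset, and any
    charsets carried by the inputs are offset into supermatrix
    coordinates (prefixed with the gene name on collision).
    """
    if not alignments:
        raise ValueError("nothing to concatenate")
    alphabet = alignments[0].alphabet
    for a in alignments[1:]:
        if a.alphabet.kind != alphabet.kind:
            raise AlignmentError("alphabet mismatch among inputs")
    if fill_missing is None:
        fill_missing = "?"
    if names is None:
        names = [f"gene{i + 1}" for i in range(len(alignments))]
    if len(names) != len(alignments):
        raise ValueError("one name per alignment required")

    taxa: list[str] = []
    for a in alignments:
        for t in a.taxa:
            if t not in taxa:
                taxa.append(t)

    total = sum(a.n_sites for a in alignments)
    matrix = np.full((len(taxa), total), fill_missing, dtype="<U1")
    charsets: dict[str, np.ndarray] = {}
    offset = 0
    for name, a in zip(names, alignments):
        span = np.arange(offset, offset + a.n_sites)
        charsets[name] = span
        for inner, idx in a.charsets.items():
            key = inner if inner not in charsets else f"{name}_{inner}"
            charsets[key] = idx + offset
        for t in a.taxa:
            matrix[taxa.index(t), offset : offset + a.n_sites] = a.row(t)
        offset += a.n_sites
    return Alignment(taxa=taxa, matrix=matrix, alphabet=alphabet, charsets=charsets)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def summarize_taxa(a: Alignment) -> list[TaxonSummary]:
    """Per-taxon missing-data percentage, G+C percentage and composition.

    "Missing" counts gaps, '?', and the fully ambiguous code (N or X);
    partial ambiguity codes are not missing.  The G+C percentage uses
    only unambiguous A/C/G/T as denominator, and composition is the
    proportion of each canonical state among unambiguous sites.
    """
    out = []
    states = a.alphabet.states
    for ti, taxon in enumerate(a.taxa):
        row = a.matrix[ti]
        n = row.size
        codes, counts = np.unique(row, return_counts=True)
        tally = dict(zip(codes.tolist(), counts.tolist()))
        n_missing = sum(
            c for code, c in tally.items() if a.alphabet.is_missing_for_counting(code)
        )
        canon = np.array([tally.get(s, 0) for s in states], dtype=float)
        n_canon = canon.sum()
        if n_canon > 0:
            comp = canon / n_canon
        else:
            comp = None
        if a.alphabet.kind == "nucleotide" and n_canon > 0:
            gc = 100.0 * (tally.get("G", 0) + tally.get("C", 0)) / n_canon
        else:
            gc = None
        out.append(
            TaxonSummary(
                taxon=taxon,
                n_sites=n,
                pct_missing=100.0 * n_missing / n if n else 0.0,
                pct_gc=gc,
                composition=comp,
            )
        )
    return out


def group_missing_stats(
    summaries: Iterable[TaxonSummary], taxa: Iterable[str] | None = None
) -> tuple[float, float]:
    """Mean and median of ``pct_missing`` over a taxon subset.

    ``taxa=None`` uses every summary.  This is the ingroup statistic of
    the taxon-sampling table (e.g. mean 4.38 / median 2.36 over the
    Streptophyta rows of the land-plant data set).
    """
    summaries = list(summaries)
    if taxa is not None:
        wanted = set(taxa)
        summaries = [s for s in summaries if s.taxon in wanted]
        if len(summaries) != len(wanted):
            missing = wanted - {s.taxon for s in summaries}
            raise KeyError(f"taxa not in summaries: {sorted(missing)}")
    if not summaries:
        raise ValueError("empty taxon subset")
    vals = np.array([s.pct_missing for s in summaries])
    return float(vals.mean()), float(np.median(vals))


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------


def translate(a: Alignment, code_table: int = 1) -> Alignment:
    """Translate an in-frame nucleotide alignment to amino acids.

    Codons containing a gap, missing code, or ambiguity that does not
    resolve to a unique amino acid become 'X'; ambiguity that does
    resolve uniquely (e.g. third-position N in a fourfold family) is
    translated.  Stop codons become 'X' (internal stops are not
    expected in curated plastid coding data and are logged).
    """
    if a.alphabet.kind != "nucleotide":
        raise AlignmentError("translation requires nucleotide data")
    if a.n_sites % 3 != 0:
        raise AlignmentError(f"{a.n_sites} sites not divisible by 3")
    if not a.frame_ok:
        raise AlignmentError("gene charsets violate codon frame")
    table = CodonTable.unambiguous_dna_by_id[code_table]
    fwd = dict(table.forward_table)
    for stop in table.stop_codons:
        fwd[stop] = "*"

    cache: dict[str, str] = {}

    def translate_codon(codon: str) -> str:
        if codon in cache:
            return cache[codon]
        aas = set()
        for c in codon:
            # gaps and '?' force a missing amino acid; ambiguity codes
            # (including N) may still resolve uniquely below
            if c in a.alphabet.gap_codes or c in a.alphabet.missing_codes:
                cache[codon] = "X"
                return "X"
        sets = [sorted(a.alphabet.code_states(c)) for c in codon]
        for x in sets[0]:
            for y in sets[1]:
                for z in sets[2]:
                    aas.add(fwd[x + y + z])
        if len(aas) == 1:
            aa = aas.pop()
            if aa == "*":
                logger.debug("stop codon %s translated as X", codon)
                aa = "X"
        else:
            aa = "X"
        cache[codon] = aa
        return aa

    n_codons = a.n_sites // 3
    out = np.empty((a.n_taxa, n_codons), dtype="<U1")
    for ti in range(a.n_taxa):
        row = a.matrix[ti]
        for ci in range(n_codons):
            out[ti, ci] = translate_codon("".join(row[3 * ci : 3 * ci + 3]))

    charsets = {}
    for name, idx in a.gene_charsets().items():
        charsets[name] = np.unique(idx // 3)
    return Alignment(
        taxa=list(a.taxa), matrix=out, alphabet=PROTEIN, charsets=charsets
    )
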