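"""Alignment-preparation operators: gap masking, RY recoding, statistics.

These are the bespoke steps applied to a whole-plastome alignment before
tree inference: converting missing-data ``N`` characters to gaps and
removing columns where more than a threshold fraction of sequences are
gapped (which deletes exactly the autapomorphic-insertion columns at the
default 99% threshold), recoding nucleotides to purine/pyrimidine states
to dampen saturation and compositional bias, and tabulating the alignment
characteristics usually reported for such matrices (length, number of
parsimony-informative sites, degapped sequence lengths).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.FastaIO import FastaWriter

__all__ = [
    "AlignmentError",
    "Alignment",
    "MaskConfig",
    "read_fasta",
    "write_fasta",
    "mask_gappy_columns",
    "ry_recode",
    "AlignmentStats",
    "alignment_stats",
]

#: DNA bases, IUPAC ambiguity codes, gap and missing.
ALPHABET = frozenset("ACGTRYSWKMBDHVN-")
_BASES = ("A", "C", "G", "T")
#: Two-state purine/pyrimidine alphabet produced by :func:`ry_recode`.
RY_ALPHABET = frozenset("RYN-")

_RY_TABLE = str.maketrans(
    {
        ch: ("R" if ch in "AG" else "Y" if ch in "CT" else ch if ch in "RY-" else "N")
        for ch in ALPHABET
    }
)


class AlignmentError(ValueError):
    """Raised on malformed alignments (ragged rows, bad characters, ...)."""


@dataclass(frozen=True)
class Alignment:
    """A rectangular taxa x columns character matrix.

    Input is case-insensitive and accepts ``U`` (treated as ``T``); rows
    are stored uppercased. Labels must be unique and non-empty.
    """

    labels: Tuple[str, ...]
    seqs: Tuple[str, ...]

    def __init__(self, labels: Sequence[str], seqs: Sequence[str]) -> None:
        labels = tuple(str(x) for x in labels)
        seqs = tuple(str(s).upper().replace("U", "T") for s in seqs)
        if len(labels) != len(seqs):
            raise AlignmentError("labels and sequences differ in number")
        if not labels:
            raise AlignmentError("empty alignment")
        if any(not lab.strip() for lab in labels):
            raise AlignmentError("empty sequence label")
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise AlignmentError(f"duplicate sequence labels: {dupes}")
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise AlignmentError(f"rows have unequal lengths: {sorted(lengths)}")
        bad = set("".join(seqs)) - ALPHABET
        if bad:
            raise AlignmentError(f"characters outside the DNA+IUPAC+gap alphabet: {sorted(bad)}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "seqs", seqs)

    @property
    def n_sequences(self) -> int:
        return len(self.labels)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def is_two_state(self) -> bool:
        """True when the matrix holds only purine/pyrimidine-coded data."""
        return set("".join(self.seqs)) <= RY_ALPHABET

    def to_array(self) -> np.ndarray:
        return np.frombuffer("".join(self.seqs).encode("ascii"), dtype="S1").reshape(
            self.n_sequences, self.length
        ).astype("U1")

    def __iter__(self):
        return iter(zip(self.labels, self.seqs))


def read_fasta(path) -> Alignment:
    """Read an aligned FASTA file; labels are taken up to the first whitespace."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no sequences in {path}")
    return Alignment([r.id for r in records], [str(r.seq) for r in records])


def write_fasta(aln: Alignment, path, wrap: int = 80) -> None:
    records = (SeqRecord(Seq(s), id=lab, description="") for lab, s in aln)
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=wrap).write_file(records)


@dataclass(frozen=True)
class MaskConfig:
    """Column-masking policy.

    A column is removed when its gap fraction is *strictly greater* than
    ``max_gap_fraction`` (the verbatim "more than 99%" rule: a column with
    exactly 99% gaps in 100 rows is kept). With ``n_as_gap`` every ``N`` is
    converted to ``-`` before counting, and stays converted in the output.
    """

    max_gap_fraction: float = 0.99
    n_as_gap: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.max_gap_fraction <= 1:
            raise ValueError("max_gap_fraction must be in [0, 1]")


def mask_gappy_columns(
    aln: Alignment, cfg: MaskConfig = MaskConfig()
) -> Tuple[Alignment, List[int]]:
    """Drop columns gappier than the threshold; returns (alignment, kept indices).

    The threshold comparison is done in exact rational arithmetic so that
    boundary columns (gap fraction equal to the threshold) are never lost
    to floating-point rounding.
    """
    arr = aln.to_array()
    if cfg.n_as_gap:
        arr[arr == "N"] = "-"
    gaps = (arr == "-").sum(axis=0)
    nrows = aln.n_sequences
    # e.g. 0.99 -> 99/100 exactly, not the nearest binary double
    threshold = Fraction(cfg.max_gap_fraction).limit_denominator(10**9)
    kept = [j for j in range(aln.length) if Fraction(int(gaps[j]), nrows) <= threshold]
    sub = arr[:, kept]
    seqs = ["".join(row) for row in sub]
    return Alignment(aln.labels, seqs), kept


def ry_recode(aln: Alignment) -> Alignment:
    """Recode purines (A, G) to R and pyrimidines (C, T) to Y.

    Gaps are untouched and existing R/Y states are fixed points, so the
    operation is idempotent. Every other ambiguity code spans or may span
    both categories and collapses to missing (``N``) — the
    information-conservative choice. Output alphabet is {R, Y, N, -}.
    """
    return Alignment(aln.labels, [s.translate(_RY_TABLE) for s in aln.seqs])


@dataclass(frozen=True)
class AlignmentStats:
    """Alignment characteristics as reported for phylogenomic matrices."""

    alignment_length: int
    n_sequences: int
    degapped_lengths: Dict[str, int]
    mean_degapped: float
    min_degapped: int
    max_degapped: int
    parsimony_informative_sites: int

    def to_row(self) -> Dict[str, object]:
        return {
            "alignment_length": self.alignment_length,
            "n_sequences": self.n_sequences,
            "n_pis": self.parsimony_informative_sites,
            "mean_degapped_length": round(self.mean_degapped, 1),
            "min_degapped_length": self.min_degapped,
            "max_degapped_length": self.max_degapped,
        }


def alignment_stats(aln: Alignment) -> AlignmentStats:
    """Length, degapped lengths and parsimony-informative site count.

    Degapped length counts characters that are neither ``-`` nor ``N``.
    A column is parsimony-informative iff at least two distinct unambiguous
    bases (A, C, G, T) each occur in at least two sequences; gaps, ``N``
    and IUPAC ambiguity codes never count as states, so a purely RY-coded
    matrix has zero parsimony-informative sites by construction.
    """
    arr = aln.to_array()
    nongap = ~((arr == "-") | (arr == "N"))
    per_seq = nongap.sum(axis=1)
    degapped = {lab: int(c) for lab, c in zip(aln.labels, per_seq)}
    if aln.length:
        counts = np.stack([(arr == b).sum(axis=0) for b in _BASES])
        pis = int((((counts >= 2).sum(axis=0)) >= 2).sum())
    else:
        pis = 0
    return AlignmentStats(
        alignment_length=aln.length,
        n_sequences=aln.n_sequences,
        degapped_lengths=degapped,
        mean_degapped=float(per_seq.mean()),
        min_degapped=int(per_seq.min()),
        max_degapped=int(per_seq.max()),
        parsimony_informative_sites=pis,
    )
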