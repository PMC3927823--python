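"""Alignment summary statistics for validating molecular input matrices.

Reads FASTA or NEXUS alignments and reports dimensions and the number of
parsimony-informative sites: columns where at least two resolved nucleotide
states (A/C/G/T) each occur in at least two sequences.  Gaps ('-'),
missing ('?') and IUPAC ambiguity codes are treated as missing data — the
conservative, deterministic choice; counts may differ slightly from tools
that resolve ambiguities as polymorphisms, and reports flag this.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

from Bio import AlignIO

logger = logging.getLogger(__name__)

RESOLVED_STATES = frozenset("ACGT")


@dataclass
class Alignment:
    """Equal-length character matrix over nucleotides plus missing symbols."""

    taxa: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment has no sequences")
        L = len(self.sequences[0])
        if L < 1:
            raise ValueError("alignment length must be >= 1")
        for taxon, seq in zip(self.taxa, self.sequences):
            if len(seq) != L:
                raise ValueError(
                    f"ragged alignment: taxon {taxon!r} has length "
                    f"{len(seq)}, expected {L}"
                )
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError(f"duplicate taxa: {dupes}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def column(self, j: int) -> str:
        return "".join(seq[j] for seq in self.sequences)


def _detect_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s:
                continue
            if s.startswith(">"):
                return "fasta"
            if s.upper().startswith("#NEXUS"):
                return "nexus"
            break
    raise ValueError(f"{path}: cannot detect alignment format (FASTA or NEXUS)")


def read_alignment(path: str | Path) -> Alignment:
    """Read a FASTA or simple NEXUS (DATA/CHARACTERS MATRIX) alignment.

    Characters are upper-cased.  NEXUS assumptions/charset blocks are
    ignored with a warning; interleaved matrices are supported.
    """
    path = Path(path)
    fmt = _detect_format(path)
    if fmt == "nexus":
        text = path.read_text()
        for blk in ("assumptions", "sets", "charset"):
            if blk in text.lower():
                warnings.warn(
                    f"{path}: NEXUS {blk} information ignored", stacklevel=2
                )
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise ValueError(f"{path}: cannot parse as {fmt}: {exc}") from exc
    taxa = [rec.id for rec in msa]
    seqs = [str(rec.seq).upper() for rec in msa]
    return Alignment(taxa, seqs)


def is_informative_column(column: str) -> bool:
    """True when >= 2 resolved states each occur in >= 2 sequences."""
    counts: dict[str, int] = {}
    for c in column.upper():
        if c in RESOLVED_STATES:
            counts[c] = counts.get(c, 0) + 1
    return sum(1 for v in counts.values() if v >= 2) >= 2


def parsimony_informative_count(aln: Alignment) -> int:
    """Number of parsimony-informative columns; ambiguity codes = missing."""
    return sum(
        1 for j in range(aln.length) if is_informative_column(aln.column(j))
    )


@dataclass
class AlignmentSummary:
    name: str
    n_taxa: int
    length: int
    informative: int

    @property
    def percent_informative(self) -> float:
        return 100.0 * self.informative / self.length


def summarize_alignment(aln: Alignment, name: str = "matrix") -> AlignmentSummary:
    return AlignmentSummary(
        name=name,
        n_taxa=aln.n_taxa,
        length=aln.length,
        informative=parsimony_informative_count(aln),
    )


def write_summary(summaries: list[AlignmentSummary], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["matrix", "taxa", "length", "informative", "percent"])
        for s in summaries:
            w.writerow(
                [s.name, s.n_taxa, s.length, s.informative,
                 f"{s.percent_informative:.1f}"]
            )
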