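"""Aligned sequence matrices and the informativeness statistics used to
stratify the replicate audit (parsimony-informative %, length, gap content).

Both nucleotide and amino-acid alignments are accepted here; the likelihood
engine itself is nucleotide-only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from Bio import SeqIO

__all__ = [
    "Alignment",
    "AlignmentSummary",
    "read_fasta",
    "write_fasta",
    "summarize_alignment",
]

DNA_STATES = "ACGT"
DNA_AMBIGUITY = set("RYSWKMBDHVN")
AA_STATES = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = set("-.?")


@dataclass
class Alignment:
    """A sequence matrix: rows are taxa, columns are sites (upper-cased)."""

    taxa: list[str]
    seqs: list[str]

    def __post_init__(self):
        if len(self.taxa) != len(self.seqs):
            raise ValueError("taxa and sequences differ in number")
        if len(self.taxa) < 2:
            raise ValueError("an alignment needs at least 2 taxa")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError(f"duplicate taxon labels: {dupes}")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            ref = len(self.seqs[0])
            bad = [t for t, s in zip(self.taxa, self.seqs) if len(s) != ref]
            raise ValueError(
                f"ragged alignment: records {bad} differ in length from "
                f"{self.taxa[0]!r} ({ref} sites)"
            )
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def matrix(self) -> np.ndarray:
        """(n_taxa, length) array of single-byte residues."""
        return np.frombuffer("".join(self.seqs).encode(), dtype="S1").reshape(
            self.n_taxa, self.length
        )

    @property
    def is_nucleotide(self) -> bool:
        residues = set("".join(self.seqs)) - GAP_CHARS
        return residues <= (set(DNA_STATES) | DNA_AMBIGUITY)


@dataclass
class AlignmentSummary:
    n_taxa: int
    length: int
    parsimony_informative: int
    parsimony_informative_pct: float
    constant_pct: float
    gap_fraction: float


def read_fasta(path) -> Alignment:
    """Read an aligned FASTA file; residues are case-folded to upper."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return Alignment(
        taxa=[r.id for r in records], seqs=[str(r.seq) for r in records]
    )


def write_fasta(aln: Alignment, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for taxon, seq in zip(aln.taxa, aln.seqs):
            fh.write(f">{taxon}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def summarize_alignment(aln: Alignment) -> AlignmentSummary:
    """Compute informativeness statistics.

    A site is parsimony-informative iff at least two distinct unambiguous
    residues each occur in at least two taxa. Gaps and ambiguity codes never
    count as states; an all-gap column counts toward length only. A constant
    site has exactly one distinct unambiguous state.
    """
    states = DNA_STATES if aln.is_nucleotide else AA_STATES
    mat = aln.matrix()
    codes = np.frombuffer(states.encode(), dtype="S1")
    # counts[s, j] = occurrences of state s in column j
    counts = np.stack([(mat == c).sum(axis=0) for c in codes])
    n_states_present = (counts > 0).sum(axis=0)
    n_duplicated = (counts >= 2).sum(axis=0)
    informative = int((n_duplicated >= 2).sum())
    constant = int((n_states_present == 1).sum())
    gap_cells = np.isin(mat, [c.encode() for c in GAP_CHARS]).sum()
    return AlignmentSummary(
        n_taxa=aln.n_taxa,
        length=aln.length,
        parsimony_informative=informative,
        parsimony_informative_pct=100.0 * informative / aln.length,
        constant_pct=100.0 * constant / aln.length,
        gap_fraction=float(gap_cells) / mat.size,
    )
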