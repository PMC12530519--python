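"""Subfamily sequence-conservation metrics for capsid-domain families.

Conservation of a protein family is summarised three ways: the percentage
of alignment columns in which every sequence carries the same residue
(the family-identity statistic), per-column information content in bits
(logo heights, R = log2(20) - H), and diagnostic positions — columns fixed
for one residue in one subfamily and a different residue in the other.
Pairwise identity between two unaligned sequences is computed by global
affine-gap alignment (BLOSUM62) followed by the same column rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


@dataclass
class ProteinAlignment:
    """Equal-length protein sequences with an optional coordinate offset.

    ``offset`` is the position (in the reference numbering, e.g. Ty1c Gag)
    of the first alignment column, so column k reports as position
    ``offset + k``.
    """

    sequences: list[str]
    labels: list[str] = field(default_factory=list)
    offset: int = 0

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment must contain at least one sequence")
        self.sequences = [s.upper() for s in self.sequences]
        length = len(self.sequences[0])
        if any(len(s) != length for s in self.sequences):
            raise ValueError("all rows must have equal length")
        allowed = set(AMINO_ACIDS + GAP)
        for s in self.sequences:
            bad = set(s) - allowed
            if bad:
                raise ValueError(f"non-protein characters in alignment: {bad}")
        if not self.labels:
            self.labels = [f"seq{i + 1}" for i in range(len(self.sequences))]
        if self.offset < 0:
            raise ValueError("offset must be non-negative")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    def column(self, k: int) -> str:
        return "".join(s[k] for s in self.sequences)


@dataclass
class AlignerConfig:
    """Global pairwise-alignment parameters (Needleman-Wunsch, affine gaps)."""

    matrix: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -0.5


def percent_identity(aln: ProteinAlignment) -> float:
    """Percentage of columns 100 % identical across all sequences.

    A column containing any gap counts as non-identical.
    """
    if len(aln.sequences) < 2:
        raise ValueError("percent identity needs at least 2 sequences")
    identical = 0
    for k in range(aln.n_columns):
        col = set(aln.column(k))
        if len(col) == 1 and GAP not in col:
            identical += 1
    return 100.0 * identical / aln.n_columns


def align_pair(
    seq_a: str, seq_b: str, config: AlignerConfig | None = None
) -> ProteinAlignment:
    """Globally align two sequences and return the two-row alignment."""
    config = config or AlignerConfig()
    for s in (seq_a, seq_b):
        if not s:
            raise ValueError("sequences must be non-empty")
        bad = set(s.upper()) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-protein characters: {bad}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(config.matrix)
    aligner.open_gap_score = config.gap_open
    aligner.extend_gap_score = config.gap_extend
    alignment = aligner.align(seq_a.upper(), seq_b.upper())[0]
    return ProteinAlignment(sequences=[str(alignment[0]), str(alignment[1])])


def pairwise_identity(
    seq_a: str, seq_b: str, config: AlignerConfig | None = None
) -> float:
    """Percent identity of two sequences after global alignment.

    Identity follows the same column rule as :func:`percent_identity`:
    matched non-gap columns over total alignment columns.
    """
    return percent_identity(align_pair(seq_a, seq_b, config))


def information_content(
    aln: ProteinAlignment, small_sample_correction: bool = False
) -> np.ndarray:
    """Per-column information content in bits: R = log2(20) - H.

    The entropy H is computed over the non-gap residues of each column;
    gap-only columns return 0 bits.  The optional small-sample correction
    subtracts e_n = 19 / (2 ln 2 * n) as in standard logo software.
    """
    r_max = np.log2(len(AMINO_ACIDS))
    out = np.zeros(aln.n_columns)
    for k in range(aln.n_columns):
        residues = [c for c in aln.column(k) if c != GAP]
        if not residues:
            out[k] = 0.0
            continue
        _, counts = np.unique(residues, return_counts=True)
        p = counts / counts.sum()
        entropy = -np.sum(p * np.log2(p))
        r = r_max - entropy
        if small_sample_correction:
            r -= (len(AMINO_ACIDS) - 1) / (2.0 * np.log(2) * len(residues))
        out[k] = max(r, 0.0)
    return out


def diagnostic_positions(
    group_a: ProteinAlignment, group_b: ProteinAlignment
) -> list[tuple[int, str, str]]:
    """Columns fixed for different residues in the two groups.

    Positions are reported in the shared coordinate frame (``offset`` of
    group A, which must match group B's).
    """
    if group_a.n_columns != group_b.n_columns:
        raise ValueError("groups must share the same column count")
    if group_a.offset != group_b.offset:
        raise ValueError("groups must share the same coordinate offset")
    out = []
    for k in range(group_a.n_columns):
        col_a = set(group_a.column(k))
        col_b = set(group_b.column(k))
        if len(col_a) == 1 and len(col_b) == 1 and GAP not in col_a | col_b:
            (res_a,), (res_b,) = col_a, col_b
            if res_a != res_b:
                out.append((group_a.offset + k, res_a, res_b))
    return out
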