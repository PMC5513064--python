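"""Pairwise alignment contracts used throughout the pipeline.

Two scoring schemes are fixed here:

* **Reference-vs-reference** (``global_aligner``): global affine alignment
  with match +1, mismatch -2 and a gap of length L costing 5 + 2L. This is
  used to align the maternal against the somatic copy of an rRNA element
  and to compute percent identity between 45S units.

* **Read-vs-reference** (``read_aligner`` / :func:`align_read`): the read is
  aligned end-to-end while the reference may be entered and left freely
  (semi-global). Matches score 0, mismatches -6, a gap of length L costs
  1 + 6L, and ambiguous bases (N) are free. A read is *accepted* when its
  best score is at least ``-0.3 x read_length``, which caps the mismatch
  load at 5% of the read. This mirrors a common short-read mapper setup for
  rRNA typing (score-min L,-0,-0.3 with read/reference gap penalties 1,6).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "GLOBAL_MATCH",
    "GLOBAL_MISMATCH",
    "GLOBAL_GAP_OPEN",
    "GLOBAL_GAP_EXTEND",
    "ReadScoreParams",
    "global_aligner",
    "global_align",
    "global_identity",
    "align_read",
]

# Global (reference-vs-reference) scheme. Gap of length L costs
# GLOBAL_GAP_OPEN + GLOBAL_GAP_EXTEND * L.
GLOBAL_MATCH = 1
GLOBAL_MISMATCH = -2
GLOBAL_GAP_OPEN = 5
GLOBAL_GAP_EXTEND = 2


@dataclass(frozen=True)
class ReadScoreParams:
    """Scoring contract for typing reads against an rRNA reference.

    ``mismatch`` and the gap costs are penalties (positive numbers);
    ``accept_slope`` sets the acceptance threshold ``-accept_slope * len``.
    """

    mismatch: float = 6.0
    gap_open: float = 1.0
    gap_extend: float = 6.0
    accept_slope: float = 0.3


def global_aligner() -> Align.PairwiseAligner:
    """A fresh global affine aligner under the reference-vs-reference scheme."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = GLOBAL_MATCH
    aligner.mismatch_score = GLOBAL_MISMATCH
    # Biopython folds the first gapped base into open_gap_score.
    aligner.open_gap_score = -(GLOBAL_GAP_OPEN + GLOBAL_GAP_EXTEND)
    aligner.extend_gap_score = -GLOBAL_GAP_EXTEND
    return aligner


def global_align(target: str, query: str) -> Align.Alignment:
    """Best global alignment of *query* against *target* (deterministic)."""
    return global_aligner().align(target, query)[0]


def global_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of the global alignment: matches / columns x 100."""
    if seq_a == seq_b:
        return 100.0
    alignment = global_align(seq_a, seq_b)
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return 100.0 * counts.identities / columns


@lru_cache(maxsize=8)
def _read_aligner(params: ReadScoreParams) -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array("ACGTN", dims=2)
    for x in "ACGT":
        for y in "ACGT":
            matrix[x, y] = 0.0 if x == y else -params.mismatch
    # N rows/columns stay at 0: ambiguous bases are not penalized.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    # Free end gaps on the reference side only: the read aligns end-to-end,
    # the reference is entered/left anywhere.
    aligner.end_deletion_score = 0.0
    return aligner


def align_read(
    read: str,
    reference: str,
    params: ReadScoreParams | None = None,
) -> tuple[float, bool]:
    """Score *read* end-to-end against *reference*; return (score, accepted).

    Accepted iff ``score >= -params.accept_slope * len(read)``.
    """
    if len(read) < 1:
        raise ValueError("read must have length >= 1")
    params = params or ReadScoreParams()
    read = read.upper().replace("U", "T")
    reference = reference.upper().replace("U", "T")
    score = _read_aligner(params).score(reference, read)
    return score, score >= -params.accept_slope * len(read)
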