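"""Developmental typing of rRNA reads.

Two complementary estimators of the maternal/somatic composition of a
sample are provided:

* **Marker scanning** (:func:`select_markers` / :func:`scan_reads`): short
  type-discriminating subsequences (26 nt by default) are derived from the
  type references — every k-mer that occurs in one type (either
  orientation) and in no other type. A read is assigned to a type when it
  contains at least one of that type's markers and none of any other type.
  This mirrors searching type-specific subsequences directly in FASTQ files
  and scales to tens of millions of reads.

* **Alignment typing** (:func:`type_profile`): each read passing the length
  filter is aligned semi-globally to the maternal and the somatic reference
  under the <=5%-mismatch acceptance contract (see
  :mod:`ribodevtyper.align`); the read is assigned to the reference with
  the higher accepted score, ties are ambiguous, double rejections
  unassigned.

Percentages are computed over assigned (maternal + somatic) reads only.
Default length filters follow the sequencing designs the method was built
for: 100 nt for 5.8S (small-RNA-seq libraries) and 25 nt for 18S/28S
(rRNA-seq libraries).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from . import align as _align
from ._seq import revcomp
from .io import read_fastq

logger = logging.getLogger(__name__)

DEFAULT_K = 26
#: reads must be at least this long to be scanned, per element
MIN_READ_LENGTH = {"5.8S": 100, "18S": 25, "28S": 25}


@dataclass(frozen=True)
class Marker:
    type_label: str
    element: str
    sequence: str
    position: int  # 1-based start on its own type reference


@dataclass
class TypingProfile:
    sample_id: str
    stage_label: str = ""
    counts: dict[str, int] = field(
        default_factory=lambda: {
            "maternal": 0, "somatic": 0, "ambiguous": 0, "unassigned": 0
        }
    )
    percent_maternal: float | None = None
    percent_somatic: float | None = None

    def finalize(self) -> "TypingProfile":
        assigned = self.counts["maternal"] + self.counts["somatic"]
        if assigned == 0:
            self.percent_maternal = self.percent_somatic = None
        else:
            self.percent_maternal = 100.0 * self.counts["maternal"] / assigned
            self.percent_somatic = 100.0 * self.counts["somatic"] / assigned
        return self

    @property
    def total_scanned(self) -> int:
        return sum(self.counts.values())


def select_markers(
    type_refs: dict[str, str],
    k: int = DEFAULT_K,
    element: str = "",
) -> list[Marker]:
    """Type-discriminating k-mers across >= 2 type references of one element.

    A k-mer of one reference is a marker when neither it nor its reverse
    complement occurs in any other type's reference (in either orientation).
    Markers are deduplicated per type. Identical references yield an empty
    list with a logged warning.
    """
    if len(type_refs) < 2:
        raise ValueError("need at least two type references")
    if k < 1:
        raise ValueError("k must be positive")

    def kmer_set(seq: str) -> set[str]:
        fwd = {seq[i : i + k] for i in range(len(seq) - k + 1)}
        return fwd | {revcomp(s) for s in fwd}

    all_kmers = {label: kmer_set(seq.upper()) for label, seq in type_refs.items()}
    markers: list[Marker] = []
    for label, seq in type_refs.items():
        seq = seq.upper()
        others: set[str] = set()
        for other_label, kmers in all_kmers.items():
            if other_label != label:
                others |= kmers
        seen: set[str] = set()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if kmer in seen or revcomp(kmer) in seen:
                continue
            if kmer not in others and revcomp(kmer) not in others:
                markers.append(Marker(label, element, kmer, i + 1))
                seen.add(kmer)
    if not markers:
        logger.warning(
            "no discriminating %d-mers found; type references may be identical", k
        )
    return markers


def build_marker_index(markers: Iterable[Marker]) -> dict[str, str | None]:
    """k-mer -> type label lookup (both orientations); None marks collisions."""
    index: dict[str, str | None] = {}
    for marker in markers:
        for kmer in (marker.sequence, revcomp(marker.sequence)):
            if kmer in index and index[kmer] != marker.type_label:
                index[kmer] = None  # ambiguous marker, should not happen
            else:
                index[kmer] = marker.type_label
    return index


def _reads_from(fastq) -> Iterable[tuple[str, str]]:
    if isinstance(fastq, (str, Path)):
        return read_fastq(fastq)
    return fastq


def scan_reads(
    fastq,
    markers: list[Marker] | dict[str, str | None],
    min_read_length: int = 25,
    k: int = DEFAULT_K,
    sample_id: str = "sample",
    stage_label: str = "",
) -> TypingProfile:
    """Assign reads to types by marker content.

    *fastq* may be a path or an iterable of ``(read_id, sequence)``. A read
    shorter than *min_read_length* is excluded from every bucket. A read
    containing markers of exactly one type is assigned to it; markers of
    two or more types make it ambiguous; no marker at all, unassigned.
    """
    index = markers if isinstance(markers, dict) else build_marker_index(markers)
    profile = TypingProfile(sample_id=sample_id, stage_label=stage_label)
    counts = profile.counts
    for _, seq in _reads_from(fastq):
        if len(seq) < min_read_length:
            continue
        found: set[str] = set()
        for i in range(len(seq) - k + 1):
            hit = index.get(seq[i : i + k])
            if hit is not None:
                found.add(hit)
                if len(found) > 1:
                    break
        if not found:
            counts["unassigned"] += 1
        elif len(found) > 1:
            counts["ambiguous"] += 1
        else:
            label = found.pop()
            if label in counts:
                counts[label] += 1
            else:
                counts[label] = 1
    return profile.finalize()


def type_profile(
    fastq,
    maternal_ref: str,
    somatic_ref: str,
    min_read_length: int = 25,
    score_params: _align.ReadScoreParams | None = None,
    sample_id: str = "sample",
    stage_label: str = "",
) -> TypingProfile:
    """Alignment-based typing of a read set against both type references.

    Each passing read is scored against both references in both
    orientations (library strandedness is not assumed); assignment goes to
    the higher accepted score, equal accepted scores are ambiguous, and a
    read rejected by both references is unassigned.
    """
    params = score_params or _align.ReadScoreParams()
    profile = TypingProfile(sample_id=sample_id, stage_label=stage_label)
    counts = profile.counts

    def best(read: str, rc: str, ref: str) -> tuple[float, bool]:
        score_fwd, ok_fwd = _align.align_read(read, ref, params)
        score_rev, ok_rev = _align.align_read(rc, ref, params)
        return max((score_fwd, ok_fwd), (score_rev, ok_rev))

    for _, seq in _reads_from(fastq):
        if len(seq) < min_read_length:
            continue
        rc = revcomp(seq)
        score_m, ok_m = best(seq, rc, maternal_ref)
        score_s, ok_s = best(seq, rc, somatic_ref)
        if not ok_m and not ok_s:
            counts["unassigned"] += 1
        elif ok_m and ok_s and score_m == score_s:
            counts["ambiguous"] += 1
        elif ok_m and (not ok_s or score_m > score_s):
            counts["maternal"] += 1
        else:
            counts["somatic"] += 1
    return profile.finalize()
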