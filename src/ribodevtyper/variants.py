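"""Comparison of maternal- vs somatic-type rRNA element sequences.

The somatic sequence is the coordinate reference: every non-identical
alignment column becomes a :class:`VariantRecord` anchored on somatic
positions, named the way the rRNA literature prints differences
(``U3780C`` for a substitution, ``78_insAC`` for an insertion after somatic
position 78). Variants are then binned into structural domains, expansion
segments and functional regions, and stem substitution pairs that preserve
base-pairing in both types are flagged as covariations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import align as _align
from ._seq import is_legal_pair, to_rna, validate_nucleotides
from .annotations import RnaTypeRef


@dataclass
class TypeAlignment:
    """A global alignment of the two type sequences of one element."""

    somatic_row: str  # gapped somatic sequence
    maternal_row: str  # gapped maternal sequence
    score: float

    def __post_init__(self) -> None:
        if len(self.somatic_row) != len(self.maternal_row):
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.somatic_row)

    def coordinate_maps(self) -> tuple[dict[int, int], dict[int, int]]:
        """(somatic->maternal, maternal->somatic) maps over match columns."""
        s2m: dict[int, int] = {}
        m2s: dict[int, int] = {}
        s_pos = m_pos = 0
        for s, m in zip(self.somatic_row, self.maternal_row):
            if s != "-":
                s_pos += 1
            if m != "-":
                m_pos += 1
            if s != "-" and m != "-":
                s2m[s_pos] = m_pos
                m2s[m_pos] = s_pos
        return s2m, m2s


@dataclass
class VariantRecord:
    """One difference between the somatic and maternal copy of an element.

    ``somatic_pos`` is 1-based; for insertions it is the somatic position
    preceding the inserted bases (0 for an insertion before position 1) and
    ``maternal_pos`` is the first inserted maternal position.
    """

    kind: str  # "substitution" | "insertion" | "deletion"
    somatic_pos: int
    somatic_bases: str
    maternal_bases: str
    maternal_pos: int
    domain_name: str = "unassigned"
    es_name: str | None = None
    sticky_name: str | None = None
    region_name: str | None = None
    paired_partner_pos: int | None = None
    is_covariation: bool = False

    def __post_init__(self) -> None:
        if self.kind == "substitution" and (
            not self.somatic_bases
            or not self.maternal_bases
            or self.somatic_bases == self.maternal_bases
        ):
            raise ValueError("substitution requires two differing non-gap bases")

    @property
    def name(self) -> str:
        """Literature-style variant name (RNA alphabet)."""
        if self.kind == "substitution":
            return (
                f"{to_rna(self.somatic_bases)}{self.somatic_pos}"
                f"{to_rna(self.maternal_bases)}"
            )
        if self.kind == "insertion":
            return f"{self.somatic_pos}_ins{to_rna(self.maternal_bases)}"
        end = self.somatic_pos + len(self.somatic_bases) - 1
        span = (
            f"{self.somatic_pos}"
            if end == self.somatic_pos
            else f"{self.somatic_pos}_{end}"
        )
        return f"{span}del{to_rna(self.somatic_bases)}"


@dataclass
class DomainVariantStats:
    domain_name: str
    n_substitutions: int
    n_indel_events: int
    domain_length: int
    percent_variant: float = field(init=False)

    def __post_init__(self) -> None:
        self.percent_variant = (
            100.0 * (self.n_substitutions + self.n_indel_events) / self.domain_length
            if self.domain_length
            else 0.0
        )


def align_types(maternal_seq: str, somatic_seq: str) -> TypeAlignment:
    """Global affine alignment of the two type sequences (somatic = reference)."""
    maternal_seq = validate_nucleotides(maternal_seq, "maternal sequence")
    somatic_seq = validate_nucleotides(somatic_seq, "somatic sequence")
    alignment = _align.global_align(somatic_seq, maternal_seq)
    return TypeAlignment(
        somatic_row=str(alignment[0]),
        maternal_row=str(alignment[1]),
        score=alignment.score,
    )


def classify_variants(
    alignment: TypeAlignment, somatic_ref: RnaTypeRef
) -> list[VariantRecord]:
    """Turn every non-identical alignment column into a VariantRecord.

    Consecutive gap columns on the same side merge into a single indel
    record. Domain/ES/sticky/region membership is looked up at the somatic
    coordinate (the insertion anchor for insertions).
    """
    records: list[VariantRecord] = []
    s_pos = m_pos = 0
    pending_kind: str | None = None
    pending: dict | None = None

    def flush() -> None:
        nonlocal pending, pending_kind
        if pending is not None:
            records.append(VariantRecord(**pending))
        pending = None
        pending_kind = None

    for s, m in zip(alignment.somatic_row, alignment.maternal_row):
        if s != "-":
            s_pos += 1
        if m != "-":
            m_pos += 1
        if s == "-" and m == "-":
            continue
        if s != "-" and m != "-":
            flush()
            if s != m:
                records.append(
                    VariantRecord(
                        kind="substitution",
                        somatic_pos=s_pos,
                        somatic_bases=s,
                        maternal_bases=m,
                        maternal_pos=m_pos,
                    )
                )
        elif s == "-":  # maternal-only base: insertion relative to somatic
            if pending_kind == "insertion" and pending["somatic_pos"] == s_pos:
                pending["maternal_bases"] += m
            else:
                flush()
                pending_kind = "insertion"
                pending = dict(
                    kind="insertion",
                    somatic_pos=s_pos,
                    somatic_bases="",
                    maternal_bases=m,
                    maternal_pos=m_pos,
                )
        else:  # somatic-only base: deletion in the maternal copy
            if (
                pending_kind == "deletion"
                and pending["somatic_pos"] + len(pending["somatic_bases"]) == s_pos
            ):
                pending["somatic_bases"] += s
            else:
                flush()
                pending_kind = "deletion"
                pending = dict(
                    kind="deletion",
                    somatic_pos=s_pos,
                    somatic_bases=s,
                    maternal_bases="",
                    maternal_pos=m_pos,
                )
    flush()

    for rec in records:
        anchor = max(rec.somatic_pos, 1)
        rec.domain_name = somatic_ref.domain_of(anchor) or "unassigned"
        rec.es_name = somatic_ref.feature_of(anchor, "ES")
        rec.sticky_name = somatic_ref.feature_of(anchor, "sticky")
        rec.region_name = somatic_ref.feature_of(anchor, "region")
        if rec.kind == "substitution":
            rec.paired_partner_pos = somatic_ref.partner_of(rec.somatic_pos)
    return records


def detect_covariations(
    variants: list[VariantRecord],
    pairing_map: list[tuple[int, int]],
    allow_wobble: bool = False,
) -> list[VariantRecord]:
    """Flag substitution pairs that change both stem partners yet keep pairing.

    A pair (i, j) is a covariation when both positions carry substitutions
    and both the somatic and the maternal base combinations form a legal
    pair (Watson-Crick, plus G.U when *allow_wobble*).
    """
    subs = {
        v.somatic_pos: v for v in variants if v.kind == "substitution"
    }
    for i, j in pairing_map:
        vi, vj = subs.get(i), subs.get(j)
        if vi is None or vj is None:
            continue
        somatic_ok = is_legal_pair(vi.somatic_bases, vj.somatic_bases, allow_wobble)
        maternal_ok = is_legal_pair(
            vi.maternal_bases, vj.maternal_bases, allow_wobble
        )
        if somatic_ok and maternal_ok:
            vi.is_covariation = vj.is_covariation = True
            vi.paired_partner_pos = j
            vj.paired_partner_pos = i
    return variants


def domain_variant_stats(
    variants: list[VariantRecord], somatic_ref: RnaTypeRef
) -> list[DomainVariantStats]:
    """Per-domain substitution/indel counts and percent variation.

    Percent variation uses the somatic domain length as denominator and
    counts each indel run as one event. A final "total" row covers the whole
    element.
    """
    lengths = somatic_ref.domain_lengths()
    subs: dict[str, int] = {}
    indels: dict[str, int] = {}
    for v in variants:
        bucket = subs if v.kind == "substitution" else indels
        bucket[v.domain_name] = bucket.get(v.domain_name, 0) + 1
    stats = [
        DomainVariantStats(
            domain_name=name,
            n_substitutions=subs.get(name, 0),
            n_indel_events=indels.get(name, 0),
            domain_length=length,
        )
        for name, length in lengths.items()
    ]
    if subs.get("unassigned") or indels.get("unassigned"):
        stats.append(
            DomainVariantStats(
                domain_name="unassigned",
                n_substitutions=subs.get("unassigned", 0),
                n_indel_events=indels.get("unassigned", 0),
                domain_length=0,
            )
        )
    stats.append(
        DomainVariantStats(
            domain_name="total",
            n_substitutions=sum(subs.values()),
            n_indel_events=sum(indels.values()),
            domain_length=len(somatic_ref.sequence),
        )
    )
    return stats


def region_diff_count(
    variants: list[VariantRecord], region: tuple[int, int]
) -> tuple[int, list[VariantRecord]]:
    """Variants whose somatic anchor falls inside *region* (1-based incl.)."""
    start, end = region
    if start > end:
        raise ValueError(f"inverted region ({start}, {end})")
    hits = [v for v in variants if start <= v.somatic_pos <= end]
    return len(hits), hits


def apply_variants(somatic_seq: str, variants: list[VariantRecord]) -> str:
    """Reconstruct the maternal sequence from the somatic one plus variants."""
    seq = list(somatic_seq)
    for v in sorted(variants, key=lambda v: v.somatic_pos, reverse=True):
        i = v.somatic_pos - 1
        if v.kind == "substitution":
            seq[i : i + 1] = list(v.maternal_bases)
        elif v.kind == "deletion":
            del seq[i : i + len(v.somatic_bases)]
        else:  # insertion after somatic_pos
            seq[i + 1 : i + 1] = list(v.maternal_bases)
    return "".join(seq)


def compare_refs(
    maternal_ref: RnaTypeRef,
    somatic_ref: RnaTypeRef,
    allow_wobble: bool = False,
) -> tuple[list[VariantRecord], list[DomainVariantStats]]:
    """Full per-element comparison: align, classify, covariations, stats."""
    alignment = align_types(maternal_ref.sequence, somatic_ref.sequence)
    variants = classify_variants(alignment, somatic_ref)
    detect_covariations(variants, somatic_ref.pairing_map, allow_wobble)
    return variants, domain_variant_stats(variants, somatic_ref)
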