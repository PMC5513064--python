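"""18S sticky-region analysis: UTR complementarity, ms-ratios, enrichment.

A "sticky" stretch of 18S rRNA is scored against mRNA 5' UTRs by
enumerating every maximal ungapped match of at least 5 nt between the UTR
and the reverse complement of the stretch (hybridization semantics; an
identity mode is available as well). Per UTR, the number of covered UTR
nucleotides against the maternal and the somatic version of the stretch is
recorded; per gene the counts are averaged over transcripts and their ratio
(the ms-ratio) computed. Overrepresentation of maternally expressed genes
among genes with ms-ratio > 1 versus < 1 is assessed with Fisher's exact
test (implemented here from the hypergeometric definition), excluding genes
whose ms-ratio is exactly one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction

from ._seq import revcomp

__all__ = [
    "StickyCount",
    "GeneMsRatio",
    "EnrichmentResult",
    "enumerate_matches",
    "stickiness",
    "gene_ms_ratios",
    "fisher_exact",
    "enrichment_test",
]


@dataclass
class StickyCount:
    transcript_id: str
    gene_id: str
    covered_nt_maternal: int
    covered_nt_somatic: int


@dataclass
class GeneMsRatio:
    gene_id: str
    mean_maternal: float
    mean_somatic: float
    ms_ratio: float  # may be inf; nan when undefined
    ratio_class: str  # "gt1" | "lt1" | "eq1" | "undefined"


@dataclass
class EnrichmentResult:
    contingency: tuple[tuple[int, int], tuple[int, int]]
    # rows: (maternal-labelled, not); columns: (gt1, lt1)
    odds_ratio: float
    p_value: float
    alternative: str
    n_excluded_eq1: int
    n_excluded_undefined: int


def enumerate_matches(
    stretch: str,
    utr: str,
    min_length: int = 5,
    mode: str = "complement",
) -> list[tuple[int, int, int, int]]:
    """All maximal ungapped matches >= *min_length* between stretch and UTR.

    In ``complement`` mode the UTR is matched against the reverse complement
    of the stretch (base-pairing semantics); in ``identity`` mode against
    the stretch itself. Returns tuples
    ``(utr_start, utr_end, stretch_start, length)``, 1-based inclusive,
    with ``stretch_start`` on the stretch's own coordinates (the 5'-most
    stretch position involved in the match). Maximal means not extendable
    on either side.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    if mode not in ("complement", "identity"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(stretch) < min_length:
        warnings.warn(
            f"stretch shorter than min_length ({len(stretch)} < {min_length}); "
            "no matches possible",
            stacklevel=2,
        )
        return []
    target = revcomp(stretch) if mode == "complement" else stretch
    n, m = len(utr), len(target)
    out: list[tuple[int, int, int, int]] = []
    # walk every diagonal of the (utr x target) match matrix
    for diag in range(-(m - 1), n):
        i = max(0, diag)  # utr index
        j = i - diag  # target index
        run = 0
        while i < n and j < m:
            if utr[i] == target[j]:
                run += 1
            else:
                if run >= min_length:
                    out.append(_match_tuple(i, j, run, m, mode))
                run = 0
            i += 1
            j += 1
        if run >= min_length:
            out.append(_match_tuple(i, j, run, m, mode))
    out.sort()
    return out


def _match_tuple(i: int, j: int, run: int, m: int, mode: str) -> tuple[int, int, int, int]:
    """Convert a run ending just before (i, j) into a 1-based match tuple."""
    utr_start = i - run + 1  # 1-based
    utr_end = i
    t_start = j - run  # 0-based start on target
    if mode == "complement":
        # target is revcomp(stretch): target[t .. t+run-1] maps to stretch
        # positions (m - t - run + 1 .. m - t), report the 5'-most one.
        stretch_start = m - t_start - run + 1
    else:
        stretch_start = t_start + 1
    return (utr_start, utr_end, stretch_start, run)


def _covered(matches: list[tuple[int, int, int, int]]) -> int:
    """Number of UTR positions covered by >= 1 match (interval union)."""
    covered = 0
    last_end = 0
    for u_start, u_end, _, _ in matches:  # sorted by utr_start
        if u_start > last_end:
            covered += u_end - u_start + 1
            last_end = u_end
        elif u_end > last_end:
            covered += u_end - last_end
            last_end = u_end
    return covered


def stickiness(
    utr: str,
    stretch_maternal: str,
    stretch_somatic: str,
    min_length: int = 5,
    mode: str = "complement",
    transcript_id: str = "",
    gene_id: str = "",
) -> StickyCount:
    """Covered-UTR-nucleotide counts against both versions of a stretch."""
    return StickyCount(
        transcript_id=transcript_id,
        gene_id=gene_id,
        covered_nt_maternal=_covered(
            enumerate_matches(stretch_maternal, utr, min_length, mode)
        ),
        covered_nt_somatic=_covered(
            enumerate_matches(stretch_somatic, utr, min_length, mode)
        ),
    )


def gene_ms_ratios(
    sticky_counts: list[StickyCount],
    tx2gene: dict[str, str],
) -> list[GeneMsRatio]:
    """Per-gene transcript-averaged counts and maternal/somatic ratio.

    The eq1 class is decided by exact rational comparison of the two means
    (cross-multiplication), never by floating-point equality.
    """
    unmapped = [c.transcript_id for c in sticky_counts if c.transcript_id not in tx2gene]
    if unmapped:
        raise ValueError(f"transcripts not mapped to any gene: {unmapped}")
    per_gene: dict[str, list[StickyCount]] = {}
    for count in sticky_counts:
        per_gene.setdefault(tx2gene[count.transcript_id], []).append(count)
    out: list[GeneMsRatio] = []
    for gene_id in sorted(per_gene):
        counts = per_gene[gene_id]
        n = len(counts)
        mat = Fraction(sum(c.covered_nt_maternal for c in counts), n)
        som = Fraction(sum(c.covered_nt_somatic for c in counts), n)
        if som == 0 and mat == 0:
            ratio, cls = float("nan"), "undefined"
        elif som == 0:
            ratio, cls = float("inf"), "gt1"
        else:
            ratio = float(mat / som)
            cls = "eq1" if mat == som else ("gt1" if mat > som else "lt1")
        out.append(
            GeneMsRatio(
                gene_id=gene_id,
                mean_maternal=float(mat),
                mean_somatic=float(som),
                ms_ratio=ratio,
                ratio_class=cls,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Fisher's exact test (hypergeometric definition)

#: Relative tolerance when comparing table probabilities for the two-sided
#: sum (mirrors the common R implementation's treatment of ties).
_TIE_RELTOL = Fraction(1, 10**7)


def _hypergeom_pmf(a: int, r1: int, r2: int, c1: int) -> Fraction:
    """P(first cell = a) for fixed margins (r1, r2) x (c1, .)."""
    return Fraction(
        math.comb(r1, a) * math.comb(r2, c1 - a), math.comb(r1 + r2, c1)
    )


def fisher_exact(
    a: int, b: int, c: int, d: int, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Exact p-value and odds ratio for the 2x2 table [[a, b], [c, d]].

    The p-value is computed from the hypergeometric distribution with all
    margins fixed: ``two-sided`` sums the probabilities of every table as or
    less probable than the observed one (with a 1e-7 relative tolerance for
    ties), ``greater``/``less`` are the one-sided tails for the first cell.
    The odds ratio is the sample odds ratio ``ad / bc`` (inf when only bc is
    zero, nan for a degenerate table).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n = a + b + c + d
    if n == 0:
        return 1.0, float("nan")
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(c1, r1)
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)

    if alternative == "greater":
        p = sum(_hypergeom_pmf(x, r1, r2, c1) for x in range(a, hi + 1))
    elif alternative == "less":
        p = sum(_hypergeom_pmf(x, r1, r2, c1) for x in range(lo, a + 1))
    else:
        observed = _hypergeom_pmf(a, r1, r2, c1)
        cutoff = observed * (1 + _TIE_RELTOL)
        p = sum(
            pmf
            for x in range(lo, hi + 1)
            if (pmf := _hypergeom_pmf(x, r1, r2, c1)) <= cutoff
        )
    return float(min(p, Fraction(1))), odds


def enrichment_test(
    gene_ratios: list[GeneMsRatio],
    labels: dict[str, str],
    alternative: str = "two-sided",
) -> EnrichmentResult:
    """Fisher test of maternal-gene overrepresentation across ratio classes.

    Builds the 2x2 table (maternally labelled yes/no x ratio class gt1/lt1),
    excluding genes with ms-ratio exactly one or with an undefined ratio.
    *labels* maps gene id to "yes"/"no".
    """
    a = b = c = d = 0
    n_eq1 = n_undef = 0
    for ratio in gene_ratios:
        if ratio.ratio_class == "eq1":
            n_eq1 += 1
            continue
        if ratio.ratio_class == "undefined":
            n_undef += 1
            continue
        if ratio.gene_id not in labels:
            raise ValueError(f"no maternal/not label for gene {ratio.gene_id}")
        maternal = labels[ratio.gene_id] == "yes"
        if ratio.ratio_class == "gt1":
            if maternal:
                a += 1
            else:
                c += 1
        else:
            if maternal:
                b += 1
            else:
                d += 1
    if a + b + c + d == 0:
        raise ValueError("no genes left after excluding eq1/undefined ratios")
    p, odds = fisher_exact(a, b, c, d, alternative)
    return EnrichmentResult(
        contingency=((a, b), (c, d)),
        odds_ratio=odds,
        p_value=p,
        alternative=alternative,
        n_excluded_eq1=n_eq1,
        n_excluded_undefined=n_undef,
    )
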