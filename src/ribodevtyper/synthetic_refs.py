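"""Synthetic maternal/somatic reference pairs with a realistic variant map.

This module builds a fully synthetic stand-in for a curated pair of
zebrafish-like rRNA type references. The sequences are random, but the
*architecture* of the differences between the maternal and the somatic copy
is planted to match what is documented for the zebrafish 45S types:

* 5.8S (158 nt): an ``AC`` insertion in the maternal copy anchored after
  somatic position 78 (maternal positions 79–80), two differences in the
  ITS2-proximal stem half (3' region) and three more central differences;
* 18S (1,869 nt somatic): five structural domains with planted variation of
  2.9% in the conserved core domain A and 10.3% in the 5' domain; a 3'
  minor-domain stem with eight paired altered nucleotides of which two
  pairs are covariations; sticky ranges "range 3-I" (maternal 188–207 /
  somatic 187–206) and "range 6-I" (maternal 776–797 / somatic 738–756),
  the coordinate offsets produced by planted maternal insertions;
* 28S (4,200 nt somatic): eight structural domains with per-domain
  variation spanning 0.6%–20.8%; exactly one difference in the PTC
  (``U3780C``), three in the GAC, and two in the SRD forming a U–A → G–C
  covariation pair; one difference in the 28S half of the ITS2-proximal
  stem.

Interval boundaries are inventions consistent with those counts — the
point of the module is a reference object on which every downstream stage
(marker selection, variant classification, domain statistics, covariation
detection, sticky analysis) can be verified against planted truth.
"""

from __future__ import annotations

import numpy as np

from .synthetic import TypePairTruth, _apply_edits, _markers_clean, _random_seq

DEFAULT_SEED = 20170801

#: Sticky-range coordinates per type (1-based inclusive, on each type's own
#: coordinates). The maternal offsets follow from the planted insertions.
STICKY_RANGES: dict[str, dict[str, dict[str, tuple[int, int]]]] = {
    "18S": {
        "range 3-I": {"maternal": (188, 207), "somatic": (187, 206)},
        "range 6-I": {"maternal": (776, 797), "somatic": (738, 756)},
    }
}

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _build_element(
    rng: np.random.Generator,
    element: str,
    length: int,
    domains: list[tuple[str, int, int]],
    random_counts: dict[str, int],
    forced_subs: dict[int, tuple[str | None, str | None]],
    insertions: dict[int, str],
    pairing_map: list[tuple[int, int]],
    force_pairs: dict[tuple[int, int], tuple[str, str]],
    es_intervals: list[tuple[str, int, int]],
    sticky_ranges: list[tuple[str, int, int]],
    regions: list[tuple[str, int, int]],
    seed: int,
) -> TypePairTruth:
    """Assemble one element pair from an explicit edit plan.

    *forced_subs* maps position -> (somatic_base | None, maternal_base | None);
    None means "keep/draw randomly, but different". *force_pairs* forces the
    somatic bases of selected stem pairs. Random substitutions are drawn per
    domain from positions outside forced/paired/region/insertion sites.
    """
    somatic = list(_random_seq(rng, length))

    # stem pairs: somatic made Watson-Crick (respecting forced bases)
    for i, j in pairing_map:
        if (i, j) in force_pairs:
            somatic[i - 1], somatic[j - 1] = force_pairs[(i, j)]
        else:
            somatic[j - 1] = _COMP[somatic[i - 1]]
    for pos, (s_base, _) in forced_subs.items():
        if s_base is not None:
            somatic[pos - 1] = s_base
    # keep insertion anchors unambiguous: the inserted run must not be
    # left- or right-shiftable along the somatic sequence
    for pos, ins in insertions.items():
        if pos + 1 <= length and somatic[pos] == ins[0]:
            somatic[pos] = next(b for b in "ACGT" if b != ins[0])
        if pos >= 1 and somatic[pos - 1] == ins[-1]:
            somatic[pos - 1] = next(b for b in "ACGT" if b != ins[-1])
    somatic_str = "".join(somatic)

    substitutions: dict[int, str] = {}
    for pos, (_, m_base) in forced_subs.items():
        old = somatic_str[pos - 1]
        if m_base is None:
            alts = [b for b in "ACGT" if b != old]
            m_base = alts[int(rng.integers(0, 3))]
        if m_base == old:
            raise ValueError(f"forced substitution at {pos} does not change {old}")
        substitutions[pos] = m_base

    blocked: set[int] = set(substitutions)
    blocked.update(p for pair in pairing_map for p in pair)
    for pos in insertions:  # keep anchors free of adjacent substitutions
        blocked.update(range(pos - 2, pos + 3))
    for _, start, end in regions:
        blocked.update(range(start, end + 1))

    for name, start, end in domains:
        count = random_counts.get(name, 0)
        if count == 0:
            continue
        pool = [p for p in range(start, end + 1) if p not in blocked]
        chosen = rng.choice(len(pool), size=count, replace=False)
        for c in chosen:
            p = pool[int(c)]
            old = somatic_str[p - 1]
            alts = [b for b in "ACGT" if b != old]
            substitutions[p] = alts[int(rng.integers(0, 3))]
            blocked.add(p)
    # random_counts may name a domain with several intervals; spend the
    # count on the first interval listed for that name (callers split it)

    maternal, records = _apply_edits(somatic_str, substitutions, insertions, {})

    domain_of = lambda pos: next(  # noqa: E731
        (name for name, s, e in domains if s <= pos <= e), "unassigned"
    )
    partner: dict[int, int] = {}
    for i, j in pairing_map:
        partner[i], partner[j] = j, i
    for rec in records:
        rec.domain_name = domain_of(max(rec.somatic_pos, 1))
        if rec.kind == "substitution":
            rec.paired_partner_pos = partner.get(rec.somatic_pos)

    covariations: list[tuple[int, int]] = []
    for i, j in pairing_map:
        if i in substitutions and j in substitutions:
            m_pair = (substitutions[i], substitutions[j])
            if m_pair in _COMP.items():
                covariations.append((i, j))
                for rec in records:
                    if rec.somatic_pos in (i, j) and rec.kind == "substitution":
                        rec.is_covariation = True

    if not _markers_clean(maternal, somatic_str, records):
        raise RuntimeError(
            f"planted {element} pair is not marker-clean for seed {seed}"
        )
    return TypePairTruth(
        base_seed=seed,
        element=element,
        maternal_seq=maternal,
        somatic_seq=somatic_str,
        planted_variants=records,
        domain_spec=list(domains),
        pairing_map=list(pairing_map),
        covariation_positions=covariations,
        es_intervals=list(es_intervals),
        sticky_ranges=list(sticky_ranges),
        regions=list(regions),
    )


def build_reference_pairs(seed: int = DEFAULT_SEED) -> dict[str, TypePairTruth]:
    """Build the synthetic 5.8S/18S/28S maternal-somatic reference pairs."""
    rng = np.random.default_rng(seed)

    pairs: dict[str, TypePairTruth] = {}

    # ---------------------------------------------------------------- 5.8S
    pairs["5.8S"] = _build_element(
        rng,
        element="5.8S",
        length=158,
        domains=[("5.8S", 1, 158)],
        random_counts={},
        forced_subs={
            55: (None, None),
            70: (None, None),
            95: (None, None),
            135: (None, None),  # ITS2-proximal stem half
            150: (None, None),
        },
        insertions={78: "AC"},  # maternal positions 79-80
        pairing_map=[],
        force_pairs={},
        es_intervals=[],
        sticky_ranges=[],
        regions=[("ITS2-proximal stem", 130, 158)],
        seed=seed,
    )

    # ----------------------------------------------------------------- 18S
    # domains tile [1, 1869]; domain A is the dispersed conserved core.
    domains_18s = [
        ("A", 1, 20),
        ("5'", 21, 600),
        ("A", 601, 640),
        ("Central", 641, 1140),
        ("A", 1141, 1180),
        ("3' major", 1181, 1600),
        ("A", 1601, 1630),
        ("3' minor", 1631, 1861),
        ("A", 1862, 1869),
    ]
    # domain A: 138 nt, 4 differences -> 2.9%
    a_random = {("A", 1, 20): 1, ("A", 601, 640): 1, ("A", 1141, 1180): 1, ("A", 1601, 1630): 1}
    # 3' minor stem: 4 pairs, all 8 positions altered, 2 pairs covariant
    pairing_18s = [(1700, 1760), (1702, 1758), (1704, 1756), (1706, 1754)]
    forced_18s: dict[int, tuple[str | None, str | None]] = {
        # sticky-range differences (5' domain and central domain)
        190: (None, None), 195: (None, None), 200: (None, None),
        740: (None, None), 748: (None, None), 752: (None, None),
        # covariation pair 1: U-A -> G-C
        1700: ("T", "G"), 1760: ("A", "C"),
        # covariation pair 2: A-U -> C-G
        1702: ("A", "C"), 1758: ("T", "G"),
        # altered but pairing-breaking in the maternal copy
        1704: ("G", "T"), 1756: ("C", "T"),
        1706: ("C", "A"), 1754: ("G", "A"),
        # ninth altered 3'-minor nucleotide, unpaired
        1710: (None, None),
    }
    ins_18s = {
        150: "G",  # +1 before range 3-I
        400: "".join(_random_seq(rng, 37)),  # ES-like maternal expansion
        745: "TGA",  # +3 inside range 6-I
    }
    pairs["18S"] = _build_element(
        rng,
        element="18S",
        length=1869,
        domains=domains_18s,
        random_counts={"5'": 55, "Central": 26, "3' major": 25, **{}},
        forced_subs=forced_18s,
        insertions=ins_18s,
        pairing_map=pairing_18s,
        force_pairs={},
        es_intervals=[("ES3S", 100, 260), ("ES6S", 680, 900)],
        sticky_ranges=[("range 3-I", 187, 206), ("range 6-I", 738, 756)],
        regions=[],
        seed=seed,
    )
    # domain A draws are split across its intervals by hand:
    pairs["18S"] = _add_domain_a(rng, pairs["18S"], a_random, seed)

    # ----------------------------------------------------------------- 28S
    domains_28s = [
        ("D0", 1, 84),
        ("D1", 85, 650),
        ("D2", 651, 1300),
        ("D3", 1301, 1900),
        ("D4", 1901, 2500),
        ("D5", 2501, 3200),
        ("D6", 3201, 3900),
        ("D7", 3901, 4117),
        ("D0", 4118, 4200),
    ]
    pairing_28s = [(4060, 4075), (4055, 4080), (4058, 4078)]
    forced_28s: dict[int, tuple[str | None, str | None]] = {
        15: (None, None),  # ITS2-proximal stem half (28S 5' end)
        1820: (None, None), 1845: (None, None), 1860: (None, None),  # GAC
        3780: ("T", "C"),  # PTC: U3780C
        # SRD covariation: U-A (somatic) -> G-C (maternal)
        4060: ("T", "G"), 4075: ("A", "C"),
    }
    pairs["28S"] = _build_element(
        rng,
        element="28S",
        length=4200,
        domains=domains_28s,
        random_counts={"D1": 17, "D2": 135, "D3": 27, "D4": 24, "D5": 42, "D6": 48, "D7": 11},
        forced_subs=forced_28s,
        insertions={},
        pairing_map=pairing_28s,
        force_pairs={(4055, 4080): ("G", "C"), (4058, 4078): ("A", "T")},
        es_intervals=[("ES7L", 700, 1100), ("ES27L", 2600, 2900)],
        sticky_ranges=[],
        regions=[
            ("ITS2-proximal stem", 1, 30),
            ("GAC", 1800, 1890),
            ("PTC", 3740, 3820),
            ("SRD", 4050, 4100),
        ],
        seed=seed,
    )

    _verify_architecture(pairs)
    return pairs


def _add_domain_a(
    rng: np.random.Generator,
    pair: TypePairTruth,
    interval_counts: dict[tuple[str, int, int], int],
    seed: int,
) -> TypePairTruth:
    """Plant the domain-A substitutions (one per listed interval)."""
    substitutions: dict[int, str] = {}
    occupied = {rec.somatic_pos for rec in pair.planted_variants}
    occupied.update(p for ij in pair.pairing_map for p in ij)
    for (name, start, end), count in interval_counts.items():
        pool = [p for p in range(start, end + 1) if p not in occupied]
        chosen = rng.choice(len(pool), size=count, replace=False)
        for c in chosen:
            p = pool[int(c)]
            old = pair.somatic_seq[p - 1]
            alts = [b for b in "ACGT" if b != old]
            substitutions[p] = alts[int(rng.integers(0, 3))]
            occupied.add(p)
    insertions = {
        rec.somatic_pos: rec.maternal_bases
        for rec in pair.planted_variants
        if rec.kind == "insertion"
    }
    all_subs = {
        rec.somatic_pos: rec.maternal_bases
        for rec in pair.planted_variants
        if rec.kind == "substitution"
    }
    all_subs.update(substitutions)
    maternal, records = _apply_edits(pair.somatic_seq, all_subs, insertions, {})
    domain_of = lambda pos: next(  # noqa: E731
        (name for name, s, e in pair.domain_spec if s <= pos <= e), "unassigned"
    )
    old_by_pos = {
        (rec.kind, rec.somatic_pos): rec for rec in pair.planted_variants
    }
    partner: dict[int, int] = {}
    for i, j in pair.pairing_map:
        partner[i], partner[j] = j, i
    for rec in records:
        rec.domain_name = domain_of(max(rec.somatic_pos, 1))
        if rec.kind == "substitution":
            rec.paired_partner_pos = partner.get(rec.somatic_pos)
            old = old_by_pos.get(("substitution", rec.somatic_pos))
            rec.is_covariation = bool(old and old.is_covariation)
    if not _markers_clean(maternal, pair.somatic_seq, records):
        raise RuntimeError(f"18S pair is not marker-clean for seed {seed}")
    return TypePairTruth(
        base_seed=pair.base_seed,
        element=pair.element,
        maternal_seq=maternal,
        somatic_seq=pair.somatic_seq,
        planted_variants=records,
        domain_spec=pair.domain_spec,
        pairing_map=pair.pairing_map,
        covariation_positions=pair.covariation_positions,
        es_intervals=pair.es_intervals,
        sticky_ranges=pair.sticky_ranges,
        regions=pair.regions,
    )


def sticky_stretches(pairs: dict[str, TypePairTruth]) -> dict[str, dict[str, str]]:
    """Cut the sticky-range stretch sequences from both 18S type sequences."""
    out: dict[str, dict[str, str]] = {}
    pair = pairs["18S"]
    for range_name, coords in STICKY_RANGES["18S"].items():
        ms, me = coords["maternal"]
        ss, se = coords["somatic"]
        out[range_name] = {
            "maternal": pair.maternal_seq[ms - 1 : me],
            "somatic": pair.somatic_seq[ss - 1 : se],
        }
    return out


def _count(pair: TypePairTruth, domain: str) -> int:
    return sum(1 for r in pair.planted_variants if r.domain_name == domain)


def _region_count(pair: TypePairTruth, region: str) -> int:
    lookup = {name: (s, e) for name, s, e in pair.regions}
    start, end = lookup[region]
    return sum(1 for r in pair.planted_variants if start <= r.somatic_pos <= end)


def _verify_architecture(pairs: dict[str, TypePairTruth]) -> None:
    """Internal consistency checks on the planted variant architecture."""
    p58, p18, p28 = pairs["5.8S"], pairs["18S"], pairs["28S"]
    ins = [r for r in p58.planted_variants if r.kind == "insertion"]
    assert len(ins) == 1 and ins[0].maternal_bases == "AC" and ins[0].maternal_pos == 79
    assert _region_count(p58, "ITS2-proximal stem") == 2
    assert _region_count(p28, "ITS2-proximal stem") == 1
    assert _region_count(p28, "PTC") == 1
    assert _region_count(p28, "GAC") == 3
    assert _region_count(p28, "SRD") == 2
    assert len(p28.covariation_positions) == 1
    assert len(p18.covariation_positions) == 2

    def percent(pair: TypePairTruth, domain: str) -> float:
        length = sum(e - s + 1 for n, s, e in pair.domain_spec if n == domain)
        return 100.0 * _count(pair, domain) / length

    assert round(percent(p18, "A"), 1) == 2.9
    assert round(percent(p18, "5'"), 1) == 10.3
    d28 = sorted({n for n, _, _ in p28.domain_spec})
    percents = [percent(p28, n) for n in d28]
    assert round(min(percents), 1) == 0.6 and round(max(percents), 1) == 20.8

    # sticky-range offsets: somatic->maternal coordinate shifts
    shift = lambda pos: sum(  # noqa: E731
        len(r.maternal_bases)
        for r in p18.planted_variants
        if r.kind == "insertion" and r.somatic_pos < pos
    )
    assert shift(187) == 1 and shift(738) == 38 and shift(757) == 41
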