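"""Seeded synthetic data with the statistical structure the pipeline assumes.

Four generators, each returning its outputs together with a machine-readable
truth record so every downstream stage can be verified without external
downloads:

* :func:`make_type_pair` — a maternal/somatic sequence pair for one rRNA
  element, with substitutions planted at per-domain rates, optional indels,
  and stem covariations (both partners swapped to a different legal pair);
* :func:`make_genome` — a genome-like contig carrying tandem
  18S–5.8S–28S transcription units separated by random spacers, with
  optional element truncations to exercise the Complete/Partial rules;
* :func:`simulate_reads` — staged read mixtures with a known maternal
  fraction and i.i.d. substitution errors;
* :func:`make_utr_set` — 5' UTR sets in which designated maternal genes
  carry planted reverse-complement matches to a chosen rRNA stretch.

All randomness flows from ``numpy.random.default_rng`` seeded with the
caller's seed; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import WC_PAIRS, WOBBLE_PAIRS, revcomp
from .annotations import Interval, RnaTypeRef
from .variants import VariantRecord

BASES = np.array(list("ACGT"))

# Minimal element lengths for a unit to count as complete (nt).
COMPLETENESS_MINIMA = {"18S": 1800, "5.8S": 150, "28S": 4000}
ELEMENT_ORDER = ("18S", "5.8S", "28S")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


# ---------------------------------------------------------------------------
# Type pairs


@dataclass
class TypePairTruth:
    base_seed: int
    element: str
    maternal_seq: str
    somatic_seq: str
    planted_variants: list[VariantRecord]
    domain_spec: list[Interval]
    pairing_map: list[tuple[int, int]]
    covariation_positions: list[tuple[int, int]]
    es_intervals: list[Interval] = field(default_factory=list)
    sticky_ranges: list[Interval] = field(default_factory=list)
    regions: list[Interval] = field(default_factory=list)

    def somatic_ref(self) -> RnaTypeRef:
        return RnaTypeRef(
            element=self.element,
            type_label="somatic",
            sequence=self.somatic_seq,
            domains=list(self.domain_spec),
            es_intervals=list(self.es_intervals),
            sticky_ranges=list(self.sticky_ranges),
            regions=list(self.regions),
            pairing_map=list(self.pairing_map),
        )

    def maternal_ref(self) -> RnaTypeRef:
        return RnaTypeRef(
            element=self.element,
            type_label="maternal",
            sequence=self.maternal_seq,
        )

    def seq_of(self, type_label: str) -> str:
        return self.maternal_seq if type_label == "maternal" else self.somatic_seq


def _check_tiling(domain_spec: list[Interval], base_length: int) -> None:
    covered = sorted((s, e) for _, s, e in domain_spec)
    pos = 1
    for start, end in covered:
        if start != pos or end < start:
            raise ValueError(
                f"domains must tile [1, {base_length}] without overlap; "
                f"gap or overlap at position {pos} (interval {start}-{end})"
            )
        pos = end + 1
    if pos != base_length + 1:
        raise ValueError(
            f"domains must tile [1, {base_length}]; coverage ends at {pos - 1}"
        )


def _apply_edits(
    somatic: str,
    substitutions: dict[int, str],
    insertions: dict[int, str],
    deletions: dict[int, int],
) -> tuple[str, list[VariantRecord]]:
    """Apply planted edits to the somatic sequence; emit truth records."""
    deleted: set[int] = set()
    for start, length in deletions.items():
        deleted.update(range(start, start + length))
    out: list[str] = []
    records: list[VariantRecord] = []
    m_pos = 0
    if 0 in insertions:
        ins = insertions[0]
        records.append(
            VariantRecord("insertion", 0, "", ins, 1)
        )
        out.append(ins)
        m_pos += len(ins)
    for s_pos in range(1, len(somatic) + 1):
        base = somatic[s_pos - 1]
        if s_pos in deletions:
            length = deletions[s_pos]
            records.append(
                VariantRecord(
                    "deletion", s_pos, somatic[s_pos - 1 : s_pos - 1 + length],
                    "", m_pos,
                )
            )
        if s_pos not in deleted:
            new = substitutions.get(s_pos, base)
            out.append(new)
            m_pos += 1
            if new != base:
                records.append(
                    VariantRecord("substitution", s_pos, base, new, m_pos)
                )
        if s_pos in insertions and s_pos != 0:
            ins = insertions[s_pos]
            records.append(
                VariantRecord("insertion", s_pos, "", ins, m_pos + 1)
            )
            out.append(ins)
            m_pos += len(ins)
    return "".join(out), records


def _markers_clean(maternal: str, somatic: str, records, k: int = 26) -> bool:
    """Check no variant-spanning k-mer of one type re-occurs in the other."""
    if not records or len(maternal) < k or len(somatic) < k:
        return True

    def kmers(seq: str) -> set[str]:
        fwd = {seq[i : i + k] for i in range(len(seq) - k + 1)}
        return fwd | {revcomp(s) for s in fwd}

    somatic_kmers = kmers(somatic)
    maternal_kmers = kmers(maternal)
    for rec in records:
        for seq, pos, other in (
            (maternal, rec.maternal_pos, somatic_kmers),
            (somatic, rec.somatic_pos, maternal_kmers),
        ):
            lo = max(0, pos - k)
            hi = min(len(seq) - k, pos - 1)
            for i in range(lo, hi + 1):
                if seq[i : i + k] in other:
                    return False
    return True


def make_type_pair(
    base_length: int,
    domain_spec: list[Interval],
    per_domain_rates: dict[str, float],
    n_covariations: int = 0,
    indel_spec: list[tuple] | None = None,
    seed: int = 0,
    element: str = "18S",
    n_pairs: int | None = None,
    allow_wobble: bool = False,
    marker_k: int = 26,
) -> TypePairTruth:
    """Generate a maternal/somatic pair differing at planted positions.

    The somatic sequence is random; the maternal copy differs by
    ``round(rate * domain_length)`` substitutions per domain (at the rate
    given in *per_domain_rates*), plus the requested covariations (stem
    pairs swapped to a different legal pair in the maternal copy) and any
    explicit indels from *indel_spec* (tuples ``("ins", somatic_pos, seq)``
    or ``("del", somatic_pos, length)``). Substitutions are re-drawn (with a
    bumped internal seed) in the rare case a planted difference recreates a
    26-mer of the other type elsewhere, which keeps marker truth clean.
    """
    for name, rate in per_domain_rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for domain {name!r} outside [0, 1]: {rate}")
    _check_tiling(domain_spec, base_length)
    indel_spec = indel_spec or []
    for spec in indel_spec:
        kind, pos, payload = spec
        if kind == "del" and int(payload) < 1:
            raise ValueError(f"deletion length below 1 nt: {spec}")
        if kind == "ins" and len(payload) < 1:
            raise ValueError(f"insertion below 1 nt: {spec}")

    if n_pairs is None:
        n_pairs = max(8, 2 * n_covariations)
    if n_covariations > n_pairs:
        raise ValueError(
            f"n_covariations={n_covariations} exceeds available pairs ({n_pairs})"
        )

    pair_pool = sorted(WC_PAIRS | (WOBBLE_PAIRS if allow_wobble else set()))

    for attempt in range(30):
        rng = np.random.default_rng([seed, attempt])
        somatic = list(_random_seq(rng, base_length))

        # stem pairs: distinct positions, somatic made Watson-Crick.
        pairing_map: list[tuple[int, int]] = []
        if n_pairs and base_length >= 2 * n_pairs:
            positions = rng.choice(base_length, size=2 * n_pairs, replace=False) + 1
            positions = [int(p) for p in positions]
            for a, b in zip(positions[::2], positions[1::2]):
                i, j = min(a, b), max(a, b)
                comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
                somatic[j - 1] = comp[somatic[i - 1]]
                pairing_map.append((i, j))
        # keep insertion anchors unambiguous (not shiftable along somatic)
        paired_positions = {p for pair in pairing_map for p in pair}
        for kind, pos, payload in indel_spec:
            if kind != "ins":
                continue
            for index, bad in ((pos - 1, payload[-1]), (pos, payload[0])):
                if 0 <= index < base_length and somatic[index] == bad:
                    if index + 1 in paired_positions:
                        raise ValueError(
                            f"insertion at {pos} collides with a stem pair"
                        )
                    alts = [b for b in "ACGT" if b != bad]
                    somatic[index] = alts[int(rng.integers(0, 3))]
        somatic_str = "".join(somatic)

        substitutions: dict[int, str] = {}
        covariation_positions: list[tuple[int, int]] = []
        cov_index = (
            rng.choice(len(pairing_map), size=n_covariations, replace=False)
            if n_covariations
            else []
        )
        for idx in cov_index:
            i, j = pairing_map[int(idx)]
            current = (somatic_str[i - 1], somatic_str[j - 1])
            choices = [
                p for p in pair_pool if p != current and p[0] != current[0] and p[1] != current[1]
            ]
            new = choices[int(rng.integers(0, len(choices)))]
            substitutions[i] = new[0]
            substitutions[j] = new[1]
            covariation_positions.append((i, j))

        # substitutions stay away from stem pairs and keep a 2-nt margin
        # around indels so every planted edit is recovered at its anchor
        blocked = {p for pair in pairing_map for p in pair}
        for kind, pos, payload in indel_spec:
            if kind == "del":
                blocked.update(range(pos - 3, pos + int(payload) + 3))
            else:
                blocked.update(range(pos - 2, pos + 3))

        for name, start, end in domain_spec:
            rate = per_domain_rates.get(name, 0.0)
            pool = [p for p in range(start, end + 1) if p not in blocked]
            n_sub = round(rate * (end - start + 1))
            if n_sub > len(pool):
                raise ValueError(
                    f"domain {name!r}: {n_sub} substitutions requested but only "
                    f"{len(pool)} positions available"
                )
            if n_sub == 0:
                continue
            chosen = rng.choice(len(pool), size=n_sub, replace=False)
            for c in chosen:
                p = pool[int(c)]
                old = somatic_str[p - 1]
                alts = [b for b in "ACGT" if b != old]
                substitutions[p] = alts[int(rng.integers(0, 3))]

        insertions = {pos: payload for kind, pos, payload in indel_spec if kind == "ins"}
        deletions = {pos: int(payload) for kind, pos, payload in indel_spec if kind == "del"}
        maternal, records = _apply_edits(somatic_str, substitutions, insertions, deletions)

        if not _markers_clean(maternal, somatic_str, records, k=marker_k):
            continue
        break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not generate a marker-clean pair in 30 attempts")

    # annotate truth records with domain membership and covariation flags
    cov_lookup = {p for pair in covariation_positions for p in pair}
    partner = {}
    for i, j in pairing_map:
        partner[i], partner[j] = j, i
    for rec in records:
        anchor = max(rec.somatic_pos, 1)
        for name, start, end in domain_spec:
            if start <= anchor <= end:
                rec.domain_name = name
                break
        if rec.kind == "substitution":
            rec.paired_partner_pos = partner.get(rec.somatic_pos)
            rec.is_covariation = rec.somatic_pos in cov_lookup

    return TypePairTruth(
        base_seed=seed,
        element=element,
        maternal_seq=maternal,
        somatic_seq=somatic_str,
        planted_variants=records,
        domain_spec=list(domain_spec),
        pairing_map=pairing_map,
        covariation_positions=covariation_positions,
    )


# ---------------------------------------------------------------------------
# Genomes


@dataclass
class UnitTruth:
    unit_id: str
    type_label: str
    strand: str
    contig_id: str
    element_intervals: dict[str, tuple[int, int]]  # contig coords, 1-based incl.
    kept_lengths: dict[str, int]
    intended_completeness: str  # "Complete" | "Partial" | "dropped"


@dataclass
class GenomeTruth:
    seed: int
    contig_id: str
    genome: dict[str, str]
    units: list[UnitTruth]


def _intended_completeness(kept: dict[str, int]) -> str:
    below = sum(
        1 for el, length in kept.items() if length < COMPLETENESS_MINIMA[el]
    )
    return "Complete" if below == 0 else ("Partial" if below == 1 else "dropped")


def make_genome(
    type_pairs: dict[str, TypePairTruth],
    units_per_type: int | dict[str, int] = 1,
    spacer_length: int = 1000,
    partial_spec: list[tuple[int, str, int]] | None = None,
    seed: int = 0,
    its_length: int = 200,
    strands: list[str] | None = None,
    contig_id: str = "sim_contig_1",
) -> GenomeTruth:
    """Emit a contig of tandem 18S–5.8S–28S units plus a truth table.

    *type_pairs* maps each element to its TypePairTruth; units are laid out
    maternal-type first, then somatic-type. *partial_spec* truncates chosen
    elements to a prefix: tuples ``(unit_index, element, keep_length)``.
    Spacer bases adjacent to a truncation junction are forced to mismatch
    the reference continuation so a truncated hit ends where planted.
    """
    missing = [el for el in ELEMENT_ORDER if el not in type_pairs]
    if missing:
        raise ValueError(f"type_pairs missing elements: {missing}")
    if isinstance(units_per_type, int):
        units_per_type = {"maternal": units_per_type, "somatic": units_per_type}
    truncate: dict[tuple[int, str], int] = {}
    for unit_index, element, keep in partial_spec or []:
        if keep < 1:
            raise ValueError(f"truncation below 1 nt: {(unit_index, element, keep)}")
        truncate[(unit_index, element)] = keep

    rng = np.random.default_rng(seed)
    layout = [
        label
        for label in ("maternal", "somatic")
        for _ in range(units_per_type.get(label, 0))
    ]
    if strands is not None and len(strands) != len(layout):
        raise ValueError("strands must have one entry per unit")

    pieces: list[str] = []
    units: list[UnitTruth] = []
    cursor = 0  # 0-based length so far

    def add_spacer(length: int, guard: str | None) -> None:
        nonlocal cursor
        spacer = list(_random_seq(rng, length))
        if guard:
            for offset, ref_base in enumerate(guard[:3]):
                if offset < len(spacer):
                    alts = [b for b in "ACGT" if b != ref_base]
                    spacer[offset] = alts[int(rng.integers(0, 3))]
        pieces.append("".join(spacer))
        cursor += length

    add_spacer(spacer_length, None)
    for index, label in enumerate(layout):
        strand = strands[index] if strands is not None else "+"
        block_parts: list[str] = []
        block_intervals: dict[str, tuple[int, int]] = {}
        kept: dict[str, int] = {}
        guard_after: str | None = None
        offset = 0
        for element in ELEMENT_ORDER:
            pair = type_pairs[element]
            full = pair.seq_of(label)
            keep = truncate.get((index, element), len(full))
            seq = full[:keep]
            kept[element] = keep
            block_intervals[element] = (offset + 1, offset + len(seq))
            block_parts.append(seq)
            offset += len(seq)
            if element != "28S":
                its = list(_random_seq(rng, its_length))
                if keep < len(full):  # guard truncation junction
                    for g, ref_base in enumerate(full[keep : keep + 3]):
                        alts = [b for b in "ACGT" if b != ref_base]
                        its[g] = alts[int(rng.integers(0, 3))]
                block_parts.append("".join(its))
                offset += its_length
            else:
                guard_after = full[keep : keep + 3] if keep < len(full) else None
        block = "".join(block_parts)
        if strand == "-":
            block = revcomp(block)
            block_len = len(block)
            block_intervals = {
                el: (block_len - e + 1, block_len - s + 1)
                for el, (s, e) in block_intervals.items()
            }
        contig_intervals = {
            el: (cursor + s, cursor + e) for el, (s, e) in block_intervals.items()
        }
        pieces.append(block)
        cursor += len(block)
        units.append(
            UnitTruth(
                unit_id=f"unit_{index + 1}",
                type_label=label,
                strand=strand,
                contig_id=contig_id,
                element_intervals=contig_intervals,
                kept_lengths=kept,
                intended_completeness=_intended_completeness(kept),
            )
        )
        add_spacer(spacer_length, guard_after if strand == "+" else None)

    return GenomeTruth(
        seed=seed,
        contig_id=contig_id,
        genome={contig_id: "".join(pieces)},
        units=units,
    )


# ---------------------------------------------------------------------------
# Reads


@dataclass
class ReadSetTruth:
    seed: int
    n_reads: int
    maternal_fraction: float
    error_rate: float
    read_length_range: tuple[int, int]
    per_read_origin: list[str]


def simulate_reads(
    type_pair: TypePairTruth,
    maternal_fraction: float,
    n_reads: int,
    read_length_range: tuple[int, int] = (30, 150),
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], ReadSetTruth]:
    """Uniformly placed substrings of the origin-type sequence, i.i.d. errors.

    Returns ``([(read_id, sequence), ...], truth)``; use
    :func:`ribodevtyper.io.write_fastq` to serialize (constant quality 'I').
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not 0.0 <= maternal_fraction <= 1.0:
        raise ValueError("maternal_fraction must lie in [0, 1]")
    lo, hi = read_length_range
    max_len = min(len(type_pair.maternal_seq), len(type_pair.somatic_seq))
    if not 1 <= lo <= hi <= max_len:
        raise ValueError(
            f"read_length_range {read_length_range} invalid for references of "
            f"length >= {max_len}"
        )
    rng = np.random.default_rng(seed)
    origins = np.where(rng.random(n_reads) < maternal_fraction, "maternal", "somatic")
    reads: list[tuple[str, str]] = []
    for i, origin in enumerate(origins):
        ref = type_pair.seq_of(str(origin))
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, len(ref) - length + 1))
        seq = list(ref[start : start + length])
        if error_rate > 0:
            hits = np.nonzero(rng.random(length) < error_rate)[0]
            for h in hits:
                alts = [b for b in "ACGT" if b != seq[h]]
                seq[h] = alts[int(rng.integers(0, 3))]
        reads.append((f"read_{i + 1}_{origin}", "".join(seq)))
    truth = ReadSetTruth(
        seed=seed,
        n_reads=n_reads,
        maternal_fraction=maternal_fraction,
        error_rate=error_rate,
        read_length_range=read_length_range,
        per_read_origin=[str(o) for o in origins],
    )
    return reads, truth


# ---------------------------------------------------------------------------
# UTR sets


@dataclass
class UtrSetTruth:
    seed: int
    genes: list[tuple[str, list[str], str]]  # (gene_id, transcript_ids, label)
    planted_matches: list[tuple[str, str, int, int, int]]
    # (transcript_id, es_target, match_length, utr_position, stretch_start)


def _scrub_background(
    rng: np.random.Generator,
    utr: list[str],
    protected: set[int],
    stretches: list[str],
    min_length: int,
) -> None:
    """Resample UTR positions (outside *protected*) that form chance matches."""
    from .sticky import enumerate_matches  # local import to avoid a cycle

    for _ in range(100):
        dirty: set[int] = set()
        seq = "".join(utr)
        for stretch in stretches:
            for u_start, u_end, _, _ in enumerate_matches(
                stretch, seq, min_length=min_length, mode="complement"
            ):
                cols = set(range(u_start - 1, u_end)) - protected
                dirty.update(cols)
        if not dirty:
            return
        for c in dirty:
            utr[c] = str(BASES[int(rng.integers(0, 4))])
    raise RuntimeError("could not scrub chance background matches")


def make_utr_set(
    n_genes: int,
    maternal_gene_fraction: float,
    es_stretch_maternal: str,
    es_stretch_somatic: str,
    planted_length_range: tuple[int, int] = (8, 14),
    affinity_bias: dict[str, float] | None = None,
    seed: int = 0,
    utr_length_range: tuple[int, int] = (150, 300),
    transcripts_per_gene: tuple[int, int] = (1, 3),
    clean_background: bool = False,
) -> tuple[dict[str, str], dict[str, str], dict[str, str], UtrSetTruth]:
    """Random 5' UTRs with planted reverse-complement matches to an ES stretch.

    Returns ``(utrs, tx2gene, labels, truth)`` where *utrs* maps transcript
    id to sequence, *tx2gene* maps transcript to gene, and *labels* maps
    gene to ``"yes"``/``"no"`` (maternally expressed). *affinity_bias* maps
    the gene label to the probability that a transcript's planted match
    targets the **maternal** stretch (default maternal 0.8 / other 0.2).
    The number of maternal genes is ``round(n_genes * fraction)`` exactly.
    With *clean_background* the UTR background is scrubbed of chance >=5-nt
    complementary matches so only planted signal remains.
    """
    lo, hi = planted_length_range
    if lo < 5:
        raise ValueError("planted lengths must be >= 5")
    if hi > min(len(es_stretch_maternal), len(es_stretch_somatic)):
        raise ValueError("ES stretch shorter than the maximum planted length")
    if affinity_bias is None:
        affinity_bias = {"maternal": 0.8, "not": 0.2}

    rng = np.random.default_rng(seed)
    n_maternal = round(n_genes * maternal_gene_fraction)
    label_list = ["yes"] * n_maternal + ["no"] * (n_genes - n_maternal)
    rng.shuffle(label_list)

    utrs: dict[str, str] = {}
    tx2gene: dict[str, str] = {}
    labels: dict[str, str] = {}
    genes: list[tuple[str, list[str], str]] = []
    planted: list[tuple[str, str, int, int, int]] = []
    stretches = {"maternal": es_stretch_maternal, "somatic": es_stretch_somatic}

    for g in range(n_genes):
        gene_id = f"gene_{g + 1:04d}"
        label = label_list[g]
        labels[gene_id] = label
        n_tx = int(rng.integers(transcripts_per_gene[0], transcripts_per_gene[1] + 1))
        tx_ids: list[str] = []
        p_maternal = affinity_bias["maternal" if label == "yes" else "not"]
        for t in range(n_tx):
            tx_id = f"tx_{g + 1:04d}_{t + 1}"
            tx_ids.append(tx_id)
            tx2gene[tx_id] = gene_id
            utr_len = int(rng.integers(utr_length_range[0], utr_length_range[1] + 1))
            utr = list(_random_seq(rng, utr_len))
            target = "maternal" if rng.random() < p_maternal else "somatic"
            length = int(rng.integers(lo, hi + 1))
            stretch = stretches[target]
            s_start = int(rng.integers(0, len(stretch) - length + 1))
            insert = revcomp(stretch[s_start : s_start + length])
            u_start = int(rng.integers(0, utr_len - length + 1))
            utr[u_start : u_start + length] = list(insert)
            if clean_background:
                protected = set(range(u_start, u_start + length))
                _scrub_background(
                    rng, utr, protected,
                    [es_stretch_maternal, es_stretch_somatic], min_length=5,
                )
            utrs[tx_id] = "".join(utr)
            planted.append((tx_id, target, length, u_start + 1, s_start + 1))
        genes.append((gene_id, tx_ids, label))

    truth = UtrSetTruth(seed=seed, genes=genes, planted_matches=planted)
    return utrs, tx2gene, labels, truth
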