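"""Discovery and classification of 45S rDNA transcription units.

A 45S unit carries the 18S, 5.8S and 28S rRNA elements in that order along
one strand. Units are located in a genome-like FASTA by seeding exact
15-mers of each element reference against the genome (both strands) and
extending seed clusters along their diagonal with an x-drop rule; clusters
whose seeds disagree on the diagonal (i.e. indel-containing copies) fall
back to a local affine alignment. Hits are assembled into units when they
lie on one contig and strand in transcription order within a span cap, and
each unit is called Complete when all three elements reach their minimal
lengths (18S >= 1,800 nt, 5.8S >= 150 nt, 28S >= 4,000 nt), Partial when
exactly one falls short, and dropped otherwise. Flanking sequence up to
1 kb on each side of a unit is extracted as the putative external
transcribed spacers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import align as _align
from ._seq import revcomp, validate_nucleotides
from .synthetic import COMPLETENESS_MINIMA, ELEMENT_ORDER

DEFAULT_SEED_K = 15
DEFAULT_MIN_IDENTITY = 80.0
DEFAULT_MIN_HIT_LENGTH = 100
DEFAULT_MAX_UNIT_SPAN = 20_000
DEFAULT_CLUSTER_GAP = 300
XDROP = 12


@dataclass
class ElementHit:
    contig_id: str
    strand: str  # "+" | "-"
    start: int  # contig coords, 1-based inclusive
    end: int
    element: str
    identity: float  # percent
    sequence: str  # transcription orientation
    n_seeds: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class RdnaUnit:
    unit_id: str
    contig_id: str
    strand: str
    element_intervals: dict[str, tuple[int, int]]
    element_seqs: dict[str, str]
    element_identities: dict[str, float]
    completeness: str  # "Complete" | "Partial"
    ets5: str = ""
    ets3: str = ""
    ets5_truncated: bool = False
    ets3_truncated: bool = False

    def concatenated_sequence(self) -> str:
        return "".join(
            self.element_seqs[el] for el in ELEMENT_ORDER if el in self.element_seqs
        )


@dataclass
class TypeCluster:
    member_unit_ids: list[str]
    representative: str
    identity_submatrix: np.ndarray = field(default_factory=lambda: np.empty(0))


# ---------------------------------------------------------------------------
# Hit finding


def _seed_clusters(
    contig: str, oriented_ref: str, k: int, cluster_gap: int
) -> list[list[tuple[int, int]]]:
    """Cluster exact k-mer seed matches (g_pos, r_pos), both 0-based."""
    index: dict[str, list[int]] = {}
    for r in range(len(oriented_ref) - k + 1):
        index.setdefault(oriented_ref[r : r + k], []).append(r)
    seeds: list[tuple[int, int]] = []
    for g in range(len(contig) - k + 1):
        for r in index.get(contig[g : g + k], ()):
            seeds.append((g, r))
    seeds.sort()
    clusters: list[list[tuple[int, int]]] = []
    for seed in seeds:
        if clusters and seed[0] - clusters[-1][-1][0] <= cluster_gap:
            clusters[-1].append(seed)
        else:
            clusters.append([seed])
    return clusters


def _xdrop_extend(
    contig: str, ref: str, diag: int, r_lo: int, r_hi: int
) -> tuple[int, int]:
    """Extend [r_lo, r_hi) on the reference along *diag* with an x-drop rule.

    Returns the extended (r_start, r_end) half-open reference interval.
    Scores match +1 / mismatch -2 and stop once the running score falls
    XDROP below its maximum; the best-scoring endpoint is kept.
    """

    def walk(start: int, step: int, limit: int) -> int:
        best, score, best_pos = 0, 0, start - step
        r = start
        while r != limit:
            g = r + diag
            if g < 0 or g >= len(contig):
                break
            score += 1 if contig[g] == ref[r] else -2
            if score > best:
                best, best_pos = score, r
            if score < best - XDROP:
                break
            r += step
        return best_pos

    r_end = walk(r_hi, +1, len(ref)) + 1
    r_start = walk(r_lo - 1, -1, -1)
    return r_start, r_end if r_end > r_start else r_hi


def _identity_ungapped(contig: str, ref: str, diag: int, r_start: int, r_end: int) -> float:
    matches = sum(
        1 for r in range(r_start, r_end) if contig[r + diag] == ref[r]
    )
    return 100.0 * matches / (r_end - r_start)


def _refine_cluster(
    contig: str, oriented_ref: str, cluster: list[tuple[int, int]], k: int
) -> tuple[int, int, float] | None:
    """Refine a seed cluster to a (g_start, g_end, identity) hit, 0-based half-open."""
    diags = {g - r for g, r in cluster}
    if len(diags) == 1:
        diag = diags.pop()
        r_lo = min(r for _, r in cluster)
        r_hi = max(r for _, r in cluster) + k
        r_start, r_end = _xdrop_extend(contig, oriented_ref, diag, r_lo, r_hi)
        identity = _identity_ungapped(contig, oriented_ref, diag, r_start, r_end)
        return r_start + diag, r_end + diag, identity
    # indel-containing copy: local alignment of the candidate window
    g_lo = min(g for g, _ in cluster)
    g_hi = max(g for g, _ in cluster) + k
    r_lo = min(r for _, r in cluster)
    r_hi = max(r for _, r in cluster) + k
    margin = 50
    w_start = max(0, g_lo - r_lo - margin)
    w_end = min(len(contig), g_hi + (len(oriented_ref) - r_hi) + margin)
    window = contig[w_start:w_end]
    aligner = _align.global_aligner()
    aligner.mode = "local"
    alignment = aligner.align(window, oriented_ref)[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return None
    g_start = w_start + int(alignment.coordinates[0][0])
    g_end = w_start + int(alignment.coordinates[0][-1])
    return g_start, g_end, 100.0 * counts.identities / columns


def find_element_hits(
    genome: dict[str, str],
    element_refs: dict[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_hit_length: int = DEFAULT_MIN_HIT_LENGTH,
    k: int = DEFAULT_SEED_K,
    cluster_gap: int = DEFAULT_CLUSTER_GAP,
) -> list[ElementHit]:
    """Locate per-element hits in *genome* on both strands.

    *genome* maps contig id to sequence (see :func:`ribodevtyper.io.read_fasta`);
    *element_refs* maps element name to one reference sequence. Hits below
    *min_identity* percent or shorter than *min_hit_length* are discarded;
    overlapping same-element hits on one contig/strand are merged into one
    maximal hit.
    """
    if not element_refs or any(not s for s in element_refs.values()):
        raise ValueError("element references must be non-empty")
    refs = {
        el: validate_nucleotides(seq, f"reference {el}")
        for el, seq in element_refs.items()
    }
    hits: list[ElementHit] = []
    for contig_id, contig in genome.items():
        contig = validate_nucleotides(contig, f"contig {contig_id!r}")
        for element, ref in refs.items():
            for strand in "+-":
                oriented = ref if strand == "+" else revcomp(ref)
                for cluster in _seed_clusters(contig, oriented, k, cluster_gap):
                    refined = _refine_cluster(contig, oriented, cluster, k)
                    if refined is None:
                        continue
                    g_start, g_end, identity = refined
                    length = g_end - g_start
                    if length < min_hit_length or identity < min_identity:
                        continue
                    segment = contig[g_start:g_end]
                    hits.append(
                        ElementHit(
                            contig_id=contig_id,
                            strand=strand,
                            start=g_start + 1,
                            end=g_end,
                            element=element,
                            identity=identity,
                            sequence=segment if strand == "+" else revcomp(segment),
                            n_seeds=len(cluster),
                        )
                    )
    return _merge_overlaps(hits, genome)


def _merge_overlaps(hits: list[ElementHit], genome: dict[str, str]) -> list[ElementHit]:
    """Merge overlapping same-element hits on one contig/strand."""
    merged: list[ElementHit] = []
    keyfunc = lambda h: (h.contig_id, h.strand, h.element, h.start)  # noqa: E731
    for hit in sorted(hits, key=keyfunc):
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and (prev.contig_id, prev.strand, prev.element)
            == (hit.contig_id, hit.strand, hit.element)
            and hit.start <= prev.end
        ):
            start, end = prev.start, max(prev.end, hit.end)
            segment = genome[prev.contig_id][start - 1 : end]
            merged[-1] = ElementHit(
                contig_id=prev.contig_id,
                strand=prev.strand,
                start=start,
                end=end,
                element=prev.element,
                identity=max(prev.identity, hit.identity),
                sequence=segment if prev.strand == "+" else revcomp(segment),
                n_seeds=prev.n_seeds + hit.n_seeds,
            )
        else:
            merged.append(hit)
    return merged


# ---------------------------------------------------------------------------
# Unit assembly


def assemble_units(
    hits: list[ElementHit],
    max_unit_span: int = DEFAULT_MAX_UNIT_SPAN,
    minima: dict[str, int] | None = None,
    return_dropped: bool = False,
):
    """Group hits into 45S units and apply the Complete/Partial rules.

    Hits on one contig and strand are walked in transcription order and
    greedily grouped while they follow the 18S -> 5.8S -> 28S order within
    *max_unit_span*. A group with every element at or above its minimal
    length is Complete; with exactly one short or missing element, Partial;
    loci with more than one sub-threshold element are dropped (returned
    separately only when *return_dropped*).
    """
    minima = minima or COMPLETENESS_MINIMA
    order_index = {el: i for i, el in enumerate(ELEMENT_ORDER)}
    units: list[RdnaUnit] = []
    dropped: list[dict[str, ElementHit]] = []

    def close(group: dict[str, ElementHit]) -> None:
        if not group:
            return
        n_below = sum(
            1
            for el in ELEMENT_ORDER
            if el not in group or group[el].length < minima[el]
        )
        if n_below > 1:
            dropped.append(group)
            return
        any_hit = next(iter(group.values()))
        units.append(
            RdnaUnit(
                unit_id=f"unit_{len(units) + 1}",
                contig_id=any_hit.contig_id,
                strand=any_hit.strand,
                element_intervals={
                    el: (h.start, h.end) for el, h in group.items()
                },
                element_seqs={el: h.sequence for el, h in group.items()},
                element_identities={el: h.identity for el, h in group.items()},
                completeness="Complete" if n_below == 0 else "Partial",
            )
        )

    by_locus: dict[tuple[str, str], list[ElementHit]] = {}
    for hit in hits:
        by_locus.setdefault((hit.contig_id, hit.strand), []).append(hit)

    for (contig_id, strand), locus_hits in sorted(by_locus.items()):
        locus_hits.sort(key=lambda h: h.start, reverse=(strand == "-"))
        group: dict[str, ElementHit] = {}
        group_span: tuple[int, int] | None = None
        last_index = -1
        for hit in locus_hits:
            index = order_index[hit.element]
            span = (
                (min(group_span[0], hit.start), max(group_span[1], hit.end))
                if group_span
                else (hit.start, hit.end)
            )
            if group and (
                index <= last_index or span[1] - span[0] + 1 > max_unit_span
            ):
                close(group)
                group, group_span = {}, None
                span = (hit.start, hit.end)
            group[hit.element] = hit
            group_span = span
            last_index = index
        close(group)

    # stable unit ids across loci
    for i, unit in enumerate(units):
        unit.unit_id = f"unit_{i + 1}"
    if return_dropped:
        return units, dropped
    return units


def extract_ets(
    unit: RdnaUnit, genome: dict[str, str], flank_length: int = 1000
) -> tuple[str, str, dict[str, bool]]:
    """Putative ETS flanks: 5' of 18S and 3' of 28S, transcription orientation.

    Flanks truncated by a contig edge are returned shorter, with the
    corresponding flag set. The unit is updated in place as well.
    """
    contig = genome[unit.contig_id]
    s18 = unit.element_intervals.get("18S")
    s28 = unit.element_intervals.get("28S")
    ets5 = ets3 = ""
    flags = {"ets5_truncated": False, "ets3_truncated": False}
    if unit.strand == "+":
        if s18:
            lo = max(0, s18[0] - 1 - flank_length)
            ets5 = contig[lo : s18[0] - 1]
            flags["ets5_truncated"] = s18[0] - 1 - flank_length < 0
        if s28:
            hi = min(len(contig), s28[1] + flank_length)
            ets3 = contig[s28[1] : hi]
            flags["ets3_truncated"] = s28[1] + flank_length > len(contig)
    else:
        if s18:
            hi = min(len(contig), s18[1] + flank_length)
            ets5 = revcomp(contig[s18[1] : hi])
            flags["ets5_truncated"] = s18[1] + flank_length > len(contig)
        if s28:
            lo = max(0, s28[0] - 1 - flank_length)
            ets3 = revcomp(contig[lo : s28[0] - 1])
            flags["ets3_truncated"] = s28[0] - 1 - flank_length < 0
    unit.ets5, unit.ets3 = ets5, ets3
    unit.ets5_truncated = flags["ets5_truncated"]
    unit.ets3_truncated = flags["ets3_truncated"]
    return ets5, ets3, flags


# ---------------------------------------------------------------------------
# Type clustering


def cluster_unit_types(
    units: list[RdnaUnit], identity_threshold: float = 97.0
) -> tuple[list[TypeCluster], np.ndarray, float]:
    """Single-linkage clustering of units on global percent identity.

    Identity is computed between concatenated element sequences under the
    global affine scheme of :mod:`ribodevtyper.align`. Returns the clusters,
    the full symmetric identity matrix (100 on the diagonal, unit order
    preserved) and its minimum off-diagonal value (100.0 for a single unit).
    """
    if not units:
        raise ValueError("need at least one unit")
    seqs = [u.concatenated_sequence() for u in units]
    n = len(units)
    matrix = np.full((n, n), 100.0)
    cache: dict[tuple[str, str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            key = (seqs[i], seqs[j]) if seqs[i] <= seqs[j] else (seqs[j], seqs[i])
            if key not in cache:
                cache[key] = _align.global_identity(key[0], key[1])
            matrix[i, j] = matrix[j, i] = cache[key]

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if matrix[i, j] >= identity_threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    clusters = [
        TypeCluster(
            member_unit_ids=[units[i].unit_id for i in members],
            representative=seqs[members[0]],
            identity_submatrix=matrix[np.ix_(members, members)],
        )
        for members in sorted(groups.values())
    ]
    off_diag = matrix[~np.eye(n, dtype=bool)]
    min_identity = float(off_diag.min()) if off_diag.size else 100.0
    return clusters, matrix, min_identity
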