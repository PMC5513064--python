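"""Reference annotations for one rRNA element of one developmental type.

An :class:`RnaTypeRef` bundles the sequence of an element (5.8S, 18S or 28S)
of one type (maternal or somatic) with interval annotations given on that
sequence's own 1-based coordinates:

* ``domains`` — the structural domains that tile the element (a domain may
  own several intervals, e.g. a dispersed core domain);
* ``es_intervals`` — expansion segments;
* ``sticky_ranges`` — 18S stretches proposed to base-pair with mRNA 5' UTRs;
* ``regions`` — other functional regions (PTC, GAC, SRD, the ITS2-proximal
  stem halves, ...);
* ``pairing_map`` — stem base pairs as (i, j) position pairs.

Annotations are exchanged as a flat TSV with columns
``element, type_label, feature_class, name, start, end`` where
``feature_class`` is one of ``domain``, ``ES``, ``sticky``, ``region`` or
``pair`` (for ``pair`` rows, start/end hold the two paired positions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._seq import validate_nucleotides

Interval = tuple[str, int, int]  # (name, start, end), 1-based inclusive

FEATURE_CLASSES = ("domain", "ES", "sticky", "region", "pair")


@dataclass
class RnaTypeRef:
    element: str  # "5.8S" | "18S" | "28S"
    type_label: str  # "maternal" | "somatic" | "undetermined"
    sequence: str
    domains: list[Interval] = field(default_factory=list)
    es_intervals: list[Interval] = field(default_factory=list)
    sticky_ranges: list[Interval] = field(default_factory=list)
    regions: list[Interval] = field(default_factory=list)
    pairing_map: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = validate_nucleotides(
            self.sequence, f"{self.element}/{self.type_label}"
        )
        n = len(self.sequence)
        for kind, intervals in (
            ("domain", self.domains),
            ("ES", self.es_intervals),
            ("sticky", self.sticky_ranges),
            ("region", self.regions),
        ):
            for name, start, end in intervals:
                if not (1 <= start <= end <= n):
                    raise ValueError(
                        f"{kind} {name!r} interval ({start}, {end}) outside "
                        f"[1, {n}] of {self.element}/{self.type_label}"
                    )
        seen: set[int] = set()
        for i, j in self.pairing_map:
            if not (1 <= i <= n and 1 <= j <= n) or i == j:
                raise ValueError(f"invalid pairing positions ({i}, {j})")
            if i in seen or j in seen:
                raise ValueError(f"position in more than one pair: ({i}, {j})")
            seen.update((i, j))

    def domain_lengths(self) -> dict[str, int]:
        """Total somatic-nt length per domain name (multi-interval aware)."""
        lengths: dict[str, int] = {}
        for name, start, end in self.domains:
            lengths[name] = lengths.get(name, 0) + (end - start + 1)
        return lengths

    def domain_of(self, pos: int) -> str | None:
        for name, start, end in self.domains:
            if start <= pos <= end:
                return name
        return None

    def feature_of(self, pos: int, which: str) -> str | None:
        intervals = {
            "ES": self.es_intervals,
            "sticky": self.sticky_ranges,
            "region": self.regions,
        }[which]
        for name, start, end in intervals:
            if start <= pos <= end:
                return name
        return None

    def partner_of(self, pos: int) -> int | None:
        for i, j in self.pairing_map:
            if pos == i:
                return j
            if pos == j:
                return i
        return None


def annotations_to_frame(refs: list[RnaTypeRef]) -> pd.DataFrame:
    rows = []
    for ref in refs:
        for cls, intervals in (
            ("domain", ref.domains),
            ("ES", ref.es_intervals),
            ("sticky", ref.sticky_ranges),
            ("region", ref.regions),
        ):
            for name, start, end in intervals:
                rows.append((ref.element, ref.type_label, cls, name, start, end))
        for i, j in ref.pairing_map:
            rows.append((ref.element, ref.type_label, "pair", "", i, j))
    return pd.DataFrame(
        rows,
        columns=["element", "type_label", "feature_class", "name", "start", "end"],
    )


def write_annotations(refs: list[RnaTypeRef], path: str | Path) -> None:
    annotations_to_frame(refs).to_csv(path, sep="\t", index=False)


def load_annotations(
    path: str | Path, sequences: dict[tuple[str, str], str]
) -> list[RnaTypeRef]:
    """Assemble RnaTypeRefs from an annotation TSV and a sequence lookup.

    *sequences* maps (element, type_label) to the reference sequence.
    Annotation rows for an (element, type_label) pair with no sequence are an
    error; sequences with no annotation rows get an annotation-free ref.
    """
    frame = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    refs: dict[tuple[str, str], RnaTypeRef] = {
        key: RnaTypeRef(element=key[0], type_label=key[1], sequence=seq)
        for key, seq in sequences.items()
    }
    for row in frame.itertuples(index=False):
        key = (row.element, row.type_label)
        if key not in refs:
            raise ValueError(f"annotation rows for unknown reference {key}")
        ref = refs[key]
        cls = row.feature_class
        if cls == "pair":
            ref.pairing_map.append((int(row.start), int(row.end)))
        elif cls == "domain":
            ref.domains.append((row.name, int(row.start), int(row.end)))
        elif cls == "ES":
            ref.es_intervals.append((row.name, int(row.start), int(row.end)))
        elif cls == "sticky":
            ref.sticky_ranges.append((row.name, int(row.start), int(row.end)))
        elif cls == "region":
            ref.regions.append((row.name, int(row.start), int(row.end)))
        else:
            raise ValueError(f"unknown feature_class {cls!r}")
    out = list(refs.values())
    for ref in out:
        ref.__post_init__()  # re-validate with intervals attached
    return out
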