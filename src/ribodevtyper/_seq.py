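"""Small sequence utilities shared across the package.

Sequences are stored in the DNA alphabet (T, not U); user-facing variant
names are rendered in RNA (U) to match the conventions of the rRNA
literature. All coordinates are 1-based inclusive unless a function says
otherwise.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Watson-Crick base pairs (DNA alphabet).
WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
#: G.U (here G.T) wobble pairs.
WOBBLE_PAIRS = {("G", "T"), ("T", "G")}

VALID_BASES = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N passes through)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    """Render a DNA string in the RNA alphabet for display."""
    return seq.replace("T", "U").replace("t", "u")


def is_legal_pair(a: str, b: str, allow_wobble: bool = False) -> bool:
    """Whether two bases can form a stem pair (Watson-Crick, optionally G.U)."""
    pair = (a.upper(), b.upper())
    return pair in WC_PAIRS or (allow_wobble and pair in WOBBLE_PAIRS)


def validate_nucleotides(seq: str, name: str = "sequence") -> str:
    """Uppercase *seq* and raise ValueError naming *name* on non-ACGT characters."""
    up = seq.upper()
    bad = set(up) - VALID_BASES
    if bad:
        raise ValueError(
            f"{name} contains non-nucleotide characters: {sorted(bad)!r}"
        )
    return up
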