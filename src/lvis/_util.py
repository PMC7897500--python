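"""Small shared helpers."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def check_dna(seq: str, *, what: str = "sequence") -> None:
    """Raise ValueError unless ``seq`` is non-empty uppercase ACGTN."""
    if not seq:
        raise ValueError(f"empty input: {what}")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{what} contains non-ACGTN characters: {sorted(bad)!r}")
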