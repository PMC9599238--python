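"""SBS96 mutation-category conventions.

Single-base substitutions are classified by the pyrimidine of the mutated
base pair (C or T), its substitution, and the two flanking bases, giving
6 x 16 = 96 categories written COSMIC-style as e.g. ``A[C>A]A``.
"""

from __future__ import annotations

_BASES = "ACGT"
_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def sbs96_categories() -> list[str]:
    """Return the 96 SBS category labels in canonical COSMIC order.

    Order is by substitution type first, then 5' flank, then 3' flank,
    each alphabetical — the order used by COSMIC catalog files.
    """
    return [
        f"{five}[{sub}]{three}"
        for sub in _SUBSTITUTIONS
        for five in _BASES
        for three in _BASES
    ]


def validate_categories(labels) -> None:
    """Raise ``ValueError`` naming the first label out of canonical order."""
    expected = sbs96_categories()
    labels = list(labels)
    if len(labels) != 96:
        raise ValueError(f"expected 96 SBS categories, got {len(labels)}")
    for got, want in zip(labels, expected):
        if got != want:
            raise ValueError(
                f"SBS category mismatch: got {got!r} where {want!r} expected"
            )
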