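"""Trinucleotide-context machinery for the 96-class substitution catalog.

Single-base substitutions are collapsed to the pyrimidine reference strand
(center base C or T); a purine-reference substitution is reverse-complemented
together with its flanking bases. Channels are ordered by substitution type
(C>A, C>G, C>T, T>A, T>C, T>G) and, within a type, alphabetically by
(5' flank, 3' flank), giving 6 x 16 = 96 channels. The 32 pyrimidine-collapsed
trinucleotides (used for background adjustment) follow the same flank order,
C-centered first.
"""

from __future__ import annotations

__all__ = [
    "BASES",
    "SUBSTITUTION_TYPES",
    "CHANNEL_LABELS",
    "TRINUCLEOTIDES",
    "revcomp",
    "channel_index",
    "channel_label",
    "channel_trinucleotide_index",
]

BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: channel i label, e.g. "A[C>T]G"
CHANNEL_LABELS = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_TYPES
    for five in BASES
    for three in BASES
)

#: pyrimidine-collapsed trinucleotides, C-centered then T-centered, flanks alphabetical
TRINUCLEOTIDES = tuple(
    f"{five}{center}{three}" for center in "CT" for five in BASES for three in BASES
)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def channel_index(ref: str, alt: str, five: str, three: str) -> int:
    """Map a substitution with flanks to its channel in [0, 96).

    Raises ValueError for anything that is not a single-base substitution of
    unambiguous bases (indels and N-containing contexts are not classifiable).
    """
    ref, alt, five, three = ref.upper(), alt.upper(), five.upper(), three.upper()
    for b in (ref, alt, five, three):
        if len(b) != 1 or b not in BASES:
            raise ValueError(f"not a classifiable substitution: {five}[{ref}>{alt}]{three}")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    if ref in "AG":  # collapse to the pyrimidine strand
        ref, alt = revcomp(ref), revcomp(alt)
        five, three = revcomp(three), revcomp(five)
    sub = SUBSTITUTION_TYPES.index(f"{ref}>{alt}")
    return sub * 16 + BASES.index(five) * 4 + BASES.index(three)


def channel_label(idx: int) -> str:
    return CHANNEL_LABELS[idx]


def channel_trinucleotide_index(idx: int) -> int:
    """Index into TRINUCLEOTIDES (0-31) of a channel's reference trinucleotide."""
    if not 0 <= idx < 96:
        raise ValueError(f"channel index out of range: {idx}")
    sub, flank = divmod(idx, 16)
    center = 0 if sub < 3 else 1  # C>N channels have a C center, T>N a T center
    return center * 16 + flank
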