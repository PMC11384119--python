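"""Promoter allele-pair fixtures for the InDel marker assay.

Promoter coordinates: -1 is the base immediately 5' of the ATG's A, so a
sequence of length P covers positions -P..-1 and position -k maps to string
index P - k.  Intervals are inclusive on both ends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_BASES = np.array(list("ACGT"))

#: a MYB-core-like element planted inside every generated insertion
_PLANTED_ELEMENT = "CAGTTA"


@dataclass(frozen=True)
class PromoterFixture:
    """A short/long promoter allele pair with one shared flanking primer pair."""

    short_allele: str
    long_allele: str
    insertion: str
    insertion_length: int
    window: tuple[int, int]  # inclusive promoter coordinates, e.g. (-332, -152)
    forward_primer: str
    reverse_primer: str

    def __post_init__(self) -> None:
        if len(self.long_allele) - len(self.short_allele) != self.insertion_length:
            raise ValueError("allele length difference must equal insertion_length")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _occurs_once(needle: str, haystack: str) -> bool:
    first = haystack.find(needle)
    return first != -1 and haystack.find(needle, first + 1) == -1


def make_promoter_fixture(
    insertion_length: int = 181,
    window: tuple[int, int] = (-332, -152),
    seed: int = 0,
    promoter_length: int = 700,
    primer_length: int = 20,
    forward_anchor: int = -600,
    reverse_anchor: int = -20,
    max_tries: int = 100,
) -> PromoterFixture:
    """Generate a promoter allele pair differing by one insertion.

    The insertion occupies the 3'-most insertion_length positions of the
    inclusive window in long-allele coordinates (defaults: positions
    -332..-152, which span exactly 181 bp).  Primers flank the window:
    the forward primer starts at forward_anchor, the reverse primer binds
    the site ending at reverse_anchor; both anneal exactly once per allele.
    """
    if insertion_length < 0:
        raise ValueError("insertion_length must be >= 0")
    lo, hi = window
    if not (lo < hi < 0):
        raise ValueError("window must be (lo, hi) with lo < hi < 0")
    span = hi - lo + 1
    if insertion_length > span:
        raise ValueError(
            f"insertion of {insertion_length} bp does not fit the {span}-bp window"
        )
    if forward_anchor >= lo or reverse_anchor <= hi:
        raise ValueError("primer anchors must flank the insertion window")
    if promoter_length < -forward_anchor:
        raise ValueError("promoter too short for the forward primer anchor")

    P = promoter_length
    # long-allele indices of the inserted block: 3'-most part of the window
    block_start = P + hi - insertion_length + 1  # index of first inserted base
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        short = _random_seq(rng, P - insertion_length)
        if insertion_length >= len(_PLANTED_ELEMENT):
            pad = insertion_length - len(_PLANTED_ELEMENT)
            insertion = _random_seq(rng, pad // 2) + _PLANTED_ELEMENT + _random_seq(
                rng, pad - pad // 2
            )
        else:
            insertion = _random_seq(rng, insertion_length)
        long = short[:block_start] + insertion + short[block_start:]

        fwd = long[P + forward_anchor : P + forward_anchor + primer_length]
        rev_site = long[P + reverse_anchor - primer_length + 1 : P + reverse_anchor + 1]
        rev = _revcomp(rev_site)
        ok = all(
            _occurs_once(fwd, allele)
            and _occurs_once(rev_site, allele)
            and _revcomp(fwd) not in allele
            and rev not in allele
            for allele in (short, long)
        )
        if ok:
            return PromoterFixture(
                short_allele=short,
                long_allele=long,
                insertion=insertion,
                insertion_length=insertion_length,
                window=window,
                forward_primer=fwd,
                reverse_primer=rev,
            )
    raise RuntimeError("could not place collision-free primers; widen the promoter")
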