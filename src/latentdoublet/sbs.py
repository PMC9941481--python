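"""SBS96 trinucleotide substitution contexts.

A single-base substitution is written "X[R>A]Y" with its 5' and 3' flanking
bases.  The canonical alphabet is pyrimidine-centered: a purine-centered
context is mapped to the opposite strand by reverse-complementing the triplet
and complementing the substituted base, giving 6 substitution types x 4 x 4
flanks = 96 classes.  Two contexts are "the same" when their canonical forms
coincide — either identical as written, or opposite-strand images of one
another.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .discovery import Doublet

__all__ = [
    "SBSContext",
    "enumerate_contexts",
    "canonical_context",
    "parse_context",
    "same_context",
    "opposite_strand",
    "doublet_context_summary",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PYRIMIDINES = {"C", "T"}
_BASES = "ACGT"
_LABEL_RE = re.compile(r"^([ACGT])\[([ACGT])\s*>\s*([ACGT])\]([ACGT])$")


@dataclass(frozen=True)
class SBSContext:
    """A canonical (pyrimidine-centered) trinucleotide substitution context."""

    five_prime: str
    ref: str
    alt: str
    three_prime: str

    def __post_init__(self) -> None:
        for b in (self.five_prime, self.ref, self.alt, self.three_prime):
            if b not in _COMPLEMENT:
                raise ValueError(f"invalid base {b!r}")
        if self.ref not in _PYRIMIDINES:
            raise ValueError("canonical context must be pyrimidine-centered")
        if self.alt == self.ref:
            raise ValueError("substitution must change the base")

    @property
    def label(self) -> str:
        return f"{self.five_prime}[{self.ref}>{self.alt}]{self.three_prime}"


def enumerate_contexts() -> list[str]:
    """The 96 canonical context labels, lexicographically sorted."""
    labels = [
        f"{five}[{ref}>{alt}]{three}"
        for ref in "CT"
        for alt in _BASES
        if alt != ref
        for five in _BASES
        for three in _BASES
    ]
    return sorted(labels)


def canonical_context(triplet: str, alt: str) -> SBSContext:
    """Canonicalize a raw (triplet, substituted base) observation.

    If the center base is a pyrimidine the context is emitted directly;
    otherwise the triplet is reverse-complemented and the substituted base
    complemented, mapping the substitution to the opposite strand.
    """
    triplet = triplet.upper()
    alt = alt.upper()
    if len(triplet) != 3 or any(b not in _COMPLEMENT for b in triplet) or alt not in _COMPLEMENT:
        raise ValueError(f"invalid context {triplet!r} alt {alt!r}")
    if alt == triplet[1]:
        raise ValueError("substituted base equals the reference base")
    if triplet[1] in _PYRIMIDINES:
        five, ref, three = triplet
    else:
        five, ref, three = (_COMPLEMENT[b] for b in reversed(triplet))
        alt = _COMPLEMENT[alt]
    return SBSContext(five_prime=five, ref=ref, alt=alt, three_prime=three)


def parse_context(label: str) -> SBSContext:
    """Parse an "X[R>A]Y" label (raw — possibly purine-centered) to canonical form."""
    m = _LABEL_RE.match(label.replace(" ", ""))
    if not m:
        raise ValueError(f"unparseable context label {label!r}")
    five, ref, alt, three = m.groups()
    return canonical_context(five + ref + three, alt)


def opposite_strand(label: str) -> str:
    """The opposite-strand image of a raw label (order reversed, bases complemented)."""
    m = _LABEL_RE.match(label.replace(" ", ""))
    if not m:
        raise ValueError(f"unparseable context label {label!r}")
    five, ref, alt, three = m.groups()
    return f"{_COMPLEMENT[three]}[{_COMPLEMENT[ref]}>{_COMPLEMENT[alt]}]{_COMPLEMENT[five]}"


def same_context(ctx1: str, ctx2: str) -> bool:
    """True iff the two contexts have identical canonical forms."""
    return parse_context(ctx1) == parse_context(ctx2)


def doublet_context_summary(doublets: list[Doublet]) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-carrier context comparison of doublet components.

    Only carriers where both components are missense with a known context are
    summarised; skipped records are tallied by reason.
    """
    rows = []
    skipped = {"non_missense": 0, "missing_context": 0}
    for d in doublets:
        for s in sorted(d.carriers):
            if d.pm_i.class_by_carrier[s] != "missense" or d.pm_j.class_by_carrier[s] != "missense":
                skipped["non_missense"] += 1
                continue
            ctx_i = d.pm_i.context_by_carrier.get(s)
            ctx_j = d.pm_j.context_by_carrier.get(s)
            if not ctx_i or not ctx_j:
                skipped["missing_context"] += 1
                continue
            rows.append(
                {
                    "gene": d.gene,
                    "pos_i": d.pos_i,
                    "pos_j": d.pos_j,
                    "carrier": s,
                    "ctx_i": parse_context(ctx_i).label,
                    "ctx_j": parse_context(ctx_j).label,
                    "same_context": same_context(ctx_i, ctx_j),
                }
            )
    frame = pd.DataFrame(
        rows, columns=["gene", "pos_i", "pos_j", "carrier", "ctx_i", "ctx_j", "same_context"]
    )
    return frame, skipped
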