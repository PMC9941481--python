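"""Post-significance doublet filters.

Three biological plausibility filters applied after Fisher/BH discovery,
each evaluated per carrier tumor:

* double-nonsense: both components nonsense in at least half of the carriers
  (two truncations of one protein cannot cooperate);
* nonsense-upstream: one component is nonsense and lies N-terminal of its
  partner in at least half of the carriers (the downstream partner is either
  a passenger on a degraded transcript or on the other allele);
* VAF overlap: the two components' VAFs sum to more than 0.5 in at least 20%
  of carrier records (VAF_i + VAF_j > 0.5 means the implied cell fractions
  exceed 100%, impossible without the mutations sharing cells).

Finally the prevalence filter splits significant doublets into the full set
and those carried by at least three tumors.
"""

from __future__ import annotations

import pandas as pd

from .discovery import Doublet

__all__ = [
    "drop_double_nonsense",
    "drop_nonsense_upstream",
    "vaf_overlap_filter",
    "prevalence_filter",
    "apply_filters",
    "filter_audit_frame",
]

FLAG_BOTH_NONSENSE = "both_nonsense"
FLAG_NONSENSE_UPSTREAM = "nonsense_upstream"
FLAG_VAF_NONOVERLAP = "vaf_nonoverlap"
FLAG_LOW_PREVALENCE = "low_prevalence"


def _both_nonsense_fraction(d: Doublet) -> float:
    carriers = d.carriers
    if not carriers:
        return 0.0
    hits = sum(
        1
        for s in carriers
        if d.pm_i.class_by_carrier[s] == "nonsense" and d.pm_j.class_by_carrier[s] == "nonsense"
    )
    return hits / len(carriers)


def _nonsense_upstream_fraction(d: Doublet) -> float:
    carriers = d.carriers
    if not carriers:
        return 0.0
    lo, hi = (d.pm_i, d.pm_j) if d.pm_i.position < d.pm_j.position else (d.pm_j, d.pm_i)
    hits = sum(1 for s in carriers if lo.class_by_carrier[s] == "nonsense")
    return hits / len(carriers)


def _overlap_fraction(d: Doublet, sum_threshold: float) -> float:
    carriers = d.carriers
    if not carriers:
        return 0.0
    hits = sum(
        1 for s in carriers if d.pm_i.vaf_by_carrier[s] + d.pm_j.vaf_by_carrier[s] > sum_threshold
    )
    return hits / len(carriers)


def drop_double_nonsense(
    doublets: list[Doublet], carrier_fraction: float = 0.5
) -> tuple[list[Doublet], list[Doublet]]:
    """Remove doublets whose components are both nonsense in >= carrier_fraction of carriers."""
    retained, removed = [], []
    for d in doublets:
        if _both_nonsense_fraction(d) >= carrier_fraction:
            d.filter_flags.add(FLAG_BOTH_NONSENSE)
            removed.append(d)
        else:
            retained.append(d)
    return retained, removed


def drop_nonsense_upstream(
    doublets: list[Doublet], carrier_fraction: float = 0.5
) -> tuple[list[Doublet], list[Doublet]]:
    """Remove doublets where the N-terminal component is nonsense in >= carrier_fraction of carriers.

    Per carrier, the pair is "nonsense-upstream" when one component is a
    nonsense mutation at a strictly smaller protein position than its partner.
    """
    retained, removed = [], []
    for d in doublets:
        if _nonsense_upstream_fraction(d) >= carrier_fraction:
            d.filter_flags.add(FLAG_NONSENSE_UPSTREAM)
            removed.append(d)
        else:
            retained.append(d)
    return retained, removed


def vaf_overlap_filter(
    doublets: list[Doublet],
    sum_threshold: float = 0.5,
    record_fraction: float = 0.2,
) -> tuple[list[Doublet], list[Doublet]]:
    """Retain doublets whose components overlap (VAF sum > sum_threshold, strict)
    in at least ``record_fraction`` of carrier records."""
    retained, removed = [], []
    for d in doublets:
        if _overlap_fraction(d, sum_threshold) >= record_fraction:
            retained.append(d)
        else:
            d.filter_flags.add(FLAG_VAF_NONOVERLAP)
            removed.append(d)
    return retained, removed


def prevalence_filter(
    doublets: list[Doublet], min_carriers: int = 3
) -> tuple[list[Doublet], list[Doublet]]:
    """Partition into (all significant, prevalent subset carried by >= min_carriers tumors)."""
    prevalent = []
    for d in doublets:
        if d.n_carriers >= min_carriers:
            prevalent.append(d)
        else:
            d.filter_flags.add(FLAG_LOW_PREVALENCE)
    return list(doublets), prevalent


def apply_filters(
    doublets: list[Doublet],
    nonsense_fraction: float = 0.5,
    sum_threshold: float = 0.5,
    record_fraction: float = 0.2,
    min_carriers: int = 3,
) -> dict[str, list[Doublet]]:
    """Run the full filter chain; returns every intermediate set keyed by stage."""
    after_nn, removed_nn = drop_double_nonsense(doublets, nonsense_fraction)
    after_up, removed_up = drop_nonsense_upstream(after_nn, nonsense_fraction)
    significant, removed_vaf = vaf_overlap_filter(after_up, sum_threshold, record_fraction)
    _, prevalent = prevalence_filter(significant, min_carriers)
    return {
        "input": doublets,
        "removed_both_nonsense": removed_nn,
        "removed_nonsense_upstream": removed_up,
        "removed_vaf_nonoverlap": removed_vaf,
        "significant": significant,
        "prevalent": prevalent,
    }


def filter_audit_frame(
    doublets: list[Doublet], sum_threshold: float = 0.5
) -> pd.DataFrame:
    """Per-doublet audit: every filter's observed carrier fraction and flags."""
    rows = [
        {
            "gene": d.gene,
            "pos_i": d.pos_i,
            "pos_j": d.pos_j,
            "n_carriers": d.n_carriers,
            "both_nonsense_fraction": _both_nonsense_fraction(d),
            "nonsense_upstream_fraction": _nonsense_upstream_fraction(d),
            "vaf_overlap_fraction": _overlap_fraction(d, sum_threshold),
            "filter_flags": ";".join(sorted(d.filter_flags)),
        }
        for d in doublets
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "pos_i", "pos_j", "n_carriers", "both_nonsense_fraction",
            "nonsense_upstream_fraction", "vaf_overlap_fraction", "filter_flags",
        ],
    )
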