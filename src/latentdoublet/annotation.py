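"""Known-driver vs latent-driver labeling and doublet classification.

A doublet component is a *known driver* (D) if it appears in a driver-mutation
catalog (matched by gene + protein position by default), otherwise a
*potential latent driver* (d).  Strength is graded against the gene-mutant
tumor group — all tumors carrying any of the gene's mutations that are
themselves present in at least three tumors:

* known driver: strong if carried by more than 10% of the gene-mutant group;
* latent driver: strong if carried by more than 1%.

Doublets are classified DD / Dd / dd by their unordered component labels, and
as co-occurring (log2 OR > 0) or mutually exclusive otherwise.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .discovery import Doublet, PositionMutation

__all__ = [
    "DEFAULT_CHEMICAL_CLASSES",
    "MutationLabel",
    "DoubletAnnotation",
    "load_catalog",
    "gene_mutant_group",
    "label_mutation",
    "annotate_doublet",
    "chemical_switch",
    "cis_trans_majority",
    "labels_to_frame",
]

#: One-letter residue -> chemical class. A partition of the 20 standard
#: residues; swappable wherever a table argument is accepted.
DEFAULT_CHEMICAL_CLASSES: dict[str, str] = {
    **{aa: "Charged" for aa in "DEKRH"},
    **{aa: "Polar" for aa in "STNQCY"},
    **{aa: "Hydrophobic" for aa in "AVLIMFWPG"},
}


@dataclass(frozen=True)
class MutationLabel:
    gene: str
    position: int
    driver_status: str  # "D" (known driver) or "d" (latent)
    strength: str  # "strong" or "weak"
    gene_mutant_frequency: float

    @property
    def is_driver(self) -> bool:
        return self.driver_status == "D"


@dataclass(frozen=True)
class DoubletAnnotation:
    composition: str  # DD / Dd / dd
    cooccurrence: str  # co-occurring / mutually_exclusive
    class_pair: str  # e.g. "missense+nonsense"
    cis_trans: str = "unknown"


def load_catalog(path) -> pd.DataFrame:
    """Read a driver catalog TSV with columns gene and protein_position (or protein_change)."""
    cat = pd.read_csv(path, sep="\t", dtype={"gene": str})
    if "protein_position" not in cat.columns and "protein_change" in cat.columns:
        cat["protein_position"] = (
            cat["protein_change"].str.extract(r"(\d+)", expand=False).astype(int)
        )
    return cat


def catalog_positions(catalog: pd.DataFrame) -> set[tuple[str, int]]:
    return set(zip(catalog["gene"], catalog["protein_position"].astype(int)))


def gene_mutant_group(
    index: dict[str, list[PositionMutation]],
    gene: str,
    min_carriers: int = 3,
) -> set[str]:
    """Tumors carrying any of the gene's mutations present in >= min_carriers tumors."""
    if gene not in index:
        warnings.warn(f"gene {gene!r} not present in position index", stacklevel=2)
        return set()
    group: set[str] = set()
    for pm in index[gene]:
        if pm.n_carriers >= min_carriers:
            group |= pm.carriers
    return group


def label_mutation(
    pm: PositionMutation,
    catalog: set[tuple[str, int]] | pd.DataFrame,
    group: set[str],
    strong_driver: float = 0.10,
    strong_latent: float = 0.01,
) -> MutationLabel:
    """Label one position-collapsed mutation against the driver catalog.

    Frequency is |carriers| / |gene-mutant group|; strength thresholds are
    strict (a driver at exactly 10% is weak).
    """
    if not group:
        raise ValueError(f"no gene-mutant tumors for {pm.gene}; cannot compute frequency")
    if isinstance(catalog, pd.DataFrame):
        catalog = catalog_positions(catalog)
    freq = pm.n_carriers / len(group)
    is_driver = (pm.gene, pm.position) in catalog
    cutoff = strong_driver if is_driver else strong_latent
    return MutationLabel(
        gene=pm.gene,
        position=pm.position,
        driver_status="D" if is_driver else "d",
        strength="strong" if freq > cutoff else "weak",
        gene_mutant_frequency=freq,
    )


def _class_pair(d: Doublet) -> str:
    pairs = Counter(
        "+".join(sorted((d.pm_i.class_by_carrier[s], d.pm_j.class_by_carrier[s])))
        for s in d.carriers
    )
    if not pairs:
        return "unknown"
    # most frequent pair; alphabetical tie-break for determinism
    return min(pairs, key=lambda k: (-pairs[k], k))


def annotate_doublet(
    doublet: Doublet,
    label_i: MutationLabel,
    label_j: MutationLabel,
    cis_trans: str = "unknown",
) -> DoubletAnnotation:
    """Classify a doublet from its component labels and odds ratio."""
    statuses = sorted((label_i.driver_status, label_j.driver_status))  # D < d
    composition = "".join(statuses)
    cooc = "co-occurring" if math.log2(doublet.odds_ratio) > 0 else "mutually_exclusive"
    return DoubletAnnotation(
        composition=composition,
        cooccurrence=cooc,
        class_pair=_class_pair(doublet),
        cis_trans=cis_trans,
    )


def chemical_switch(
    ref_aa: str,
    alt_aa: str,
    table: dict[str, str] | None = None,
) -> str:
    """Chemical-class switch label "X>Y" for a missense change; "not applicable"
    for stop codons or frameshift markers."""
    table = table if table is not None else DEFAULT_CHEMICAL_CLASSES
    if ref_aa not in table or alt_aa not in table:
        return "not applicable"
    return f"{table[ref_aa]}>{table[alt_aa]}"


def cis_trans_majority(per_carrier_calls: list[str]) -> str:
    """Majority vote over externally supplied per-carrier cis/trans calls.

    Ties are inconclusive; an empty call list is unknown.
    """
    if not per_carrier_calls:
        return "unknown"
    n_cis = sum(1 for c in per_carrier_calls if c == "cis")
    n_trans = sum(1 for c in per_carrier_calls if c == "trans")
    if n_cis > n_trans:
        return "cis"
    if n_trans > n_cis:
        return "trans"
    return "inconclusive"


def labels_to_frame(labels: list[MutationLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": l.gene,
                "position": l.position,
                "status": l.driver_status,
                "strength": l.strength,
                "gene_mutant_frequency": l.gene_mutant_frequency,
            }
            for l in labels
        ],
        columns=["gene", "position", "status", "strength", "gene_mutant_frequency"],
    )
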