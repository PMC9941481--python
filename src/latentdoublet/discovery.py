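"""Same-gene double-mutation discovery.

Mutations are collapsed by (gene, protein position) regardless of the mutant
residue.  For every unordered pair of positions within a gene that are each
carried by at least ``min_carriers`` tumors, a 2x2 contingency table is built
over the full cohort:

    a = tumors carrying both positions        b = only the first
    c = only the second                       d = N - (a + b + c)

Each table is tested with a two-sided Fisher exact test and the p-values are
corrected over the full candidate family with Benjamini-Hochberg; doublets
with q below the cutoff (default 0.1) are reported together with their odds
ratio a*d / (b*c) (Haldane-Anscombe 0.5 added to every cell when b or c is
zero, flagged in the output).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .maf_io import Cohort

__all__ = [
    "PositionMutation",
    "ContingencyTable",
    "Doublet",
    "index_positions",
    "enumerate_candidates",
    "build_contingency",
    "test_candidates",
    "doublets_to_frame",
]


@dataclass(frozen=True)
class PositionMutation:
    """A position-collapsed mutation: one (gene, residue) with its carriers.

    A sample carrying two different mutant residues at the same position
    contributes once; its recorded VAF is the maximum over its records there
    (alleles at one site in one clone are alternatives, not additive).
    """

    gene: str
    position: int
    carriers: frozenset[str]
    class_by_carrier: dict[str, str] = field(hash=False)
    vaf_by_carrier: dict[str, float] = field(hash=False)
    context_by_carrier: dict[str, str | None] = field(default_factory=dict, hash=False)

    def __post_init__(self) -> None:
        if not self.carriers:
            raise ValueError("PositionMutation requires at least one carrier")
        if set(self.class_by_carrier) != set(self.carriers) or set(self.vaf_by_carrier) != set(self.carriers):
            raise ValueError("per-carrier maps must be keyed exactly by the carrier set")

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_list(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


@dataclass
class Doublet:
    """A candidate same-gene double mutation with its test results."""

    gene: str
    pm_i: PositionMutation
    pm_j: PositionMutation
    table: ContingencyTable
    p_value: float
    q_value: float
    odds_ratio: float
    or_corrected: bool
    filter_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.pm_i.position == self.pm_j.position:
            raise ValueError("doublet components must differ in position")

    @property
    def pos_i(self) -> int:
        return self.pm_i.position

    @property
    def pos_j(self) -> int:
        return self.pm_j.position

    @property
    def carriers(self) -> frozenset[str]:
        return self.pm_i.carriers & self.pm_j.carriers

    @property
    def n_carriers(self) -> int:
        return self.table.a


def index_positions(cohort: Cohort) -> dict[str, list[PositionMutation]]:
    """Build the per-gene index of position-collapsed mutations."""
    out: dict[str, list[PositionMutation]] = {}
    df = cohort.df
    if df.empty:
        return out
    grouped = df.groupby(["gene", "protein_position"], sort=True)
    for (gene, pos), grp in grouped:
        classes: dict[str, str] = {}
        vafs: dict[str, float] = {}
        ctxs: dict[str, str | None] = {}
        for row in grp.itertuples(index=False):
            s = row.sample_id
            if s not in vafs or row.vaf > vafs[s]:
                vafs[s] = row.vaf
                classes[s] = row.variant_class
                ctxs[s] = row.context if isinstance(row.context, str) else None
        pm = PositionMutation(
            gene=gene,
            position=int(pos),
            carriers=frozenset(vafs),
            class_by_carrier=classes,
            vaf_by_carrier=vafs,
            context_by_carrier=ctxs,
        )
        out.setdefault(gene, []).append(pm)
    return out


def enumerate_candidates(
    index: dict[str, list[PositionMutation]],
    min_carriers: int = 3,
) -> list[tuple[PositionMutation, PositionMutation]]:
    """All unordered same-gene pairs of positions each carried by >= min_carriers tumors.

    The total equals sum over genes of C(m_g, 2), m_g = eligible positions.
    Pairs are ordered so that the lower protein position comes first.
    """
    pairs: list[tuple[PositionMutation, PositionMutation]] = []
    for gene in sorted(index):
        eligible = sorted(
            (pm for pm in index[gene] if pm.n_carriers >= min_carriers),
            key=lambda pm: pm.position,
        )
        pairs.extend(combinations(eligible, 2))
    return pairs


def build_contingency(
    pair: tuple[PositionMutation, PositionMutation],
    cohort: Cohort,
) -> ContingencyTable:
    """Contingency table of a candidate pair over the full cohort."""
    pm_i, pm_j = pair
    a = len(pm_i.carriers & pm_j.carriers)
    b = len(pm_i.carriers - pm_j.carriers)
    c = len(pm_j.carriers - pm_i.carriers)
    n = cohort.N
    d = n - (a + b + c)
    if d < 0:
        raise ValueError(
            f"cohort has N={n} samples but the pair spans {a + b + c} carriers; corrupt cohort"
        )
    return ContingencyTable(a, b, c, d)


def _odds_ratio(t: ContingencyTable) -> tuple[float, bool]:
    if t.b == 0 or t.c == 0:
        a, b, c, d = (x + 0.5 for x in (t.a, t.b, t.c, t.d))
        return (a * d) / (b * c), True
    return (t.a * t.d) / (t.b * t.c), False


def test_candidates(
    candidates: list[tuple[PositionMutation, PositionMutation]],
    cohort: Cohort,
    q_max: float = 0.1,
    alternative: str = "two-sided",
    return_all: bool = False,
) -> list[Doublet]:
    """Fisher exact test per candidate pair, BH correction over the whole family.

    Parameters
    ----------
    candidates
        One testing family: all pairs from a single enumeration run (the
        correction spans every candidate, not only those observed together).
    q_max
        BH cutoff; doublets with ``q < q_max`` are returned.
    return_all
        If true, return every tested candidate regardless of q (for audit).
    """
    if not candidates:
        return []
    tables = [build_contingency(pair, cohort) for pair in candidates]
    pvals = [fisher_exact(t.as_list(), alternative=alternative)[1] for t in tables]
    qvals = multipletests(pvals, method="fdr_bh")[1]
    out: list[Doublet] = []
    for pair, table, p, q in zip(candidates, tables, pvals, qvals):
        if not return_all and not q < q_max:
            continue
        orv, corrected = _odds_ratio(table)
        pm_i, pm_j = pair
        out.append(
            Doublet(
                gene=pm_i.gene,
                pm_i=pm_i,
                pm_j=pm_j,
                table=table,
                p_value=float(p),
                q_value=float(q),
                odds_ratio=orv,
                or_corrected=corrected,
            )
        )
    return out


def doublets_to_frame(doublets: list[Doublet]) -> pd.DataFrame:
    """Tabular view: gene, positions, cells, p, q, OR, carriers (semicolon-joined)."""
    rows = [
        {
            "gene": d.gene,
            "pos_i": d.pos_i,
            "pos_j": d.pos_j,
            "a": d.table.a,
            "b": d.table.b,
            "c": d.table.c,
            "d": d.table.d,
            "p": d.p_value,
            "q": d.q_value,
            "OR": d.odds_ratio,
            "or_corrected": d.or_corrected,
            "filter_flags": ";".join(sorted(d.filter_flags)),
            "carriers": ";".join(sorted(d.carriers)),
        }
        for d in doublets
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "pos_i", "pos_j", "a", "b", "c", "d",
            "p", "q", "OR", "or_corrected", "filter_flags", "carriers",
        ],
    )
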