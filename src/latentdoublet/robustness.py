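"""Hyper-mutated sample handling and the permutation burden test.

A sample is hyper-mutated when its non-synonymous mutation count strictly
exceeds Q3 + 8 x IQR of the cohort's per-sample counts (quartiles by linear
interpolation of the order statistics).  Doublets carried by hyper-mutated
samples are excluded, and the remaining doublets are re-tested with Fisher's
exact test in the non-hyper-mutated cohort.

The permutation burden test compares the mean non-synonymous mutation count
of double-mutant tumors against the remaining gene-mutant tumors:

    T = mean(Double) - mean(Single)

Group labels are shuffled B times (default 5000) holding the counts fixed;
the p-value is the fraction of permutations whose statistic strictly exceeds
the observed one, p = N_exceed / B (no add-one correction, so p may be 0;
the add-one alternative is reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .discovery import ContingencyTable, Doublet
from .maf_io import Cohort

__all__ = [
    "BurdenProfile",
    "PermutationResult",
    "mutation_counts",
    "flag_hypermutated",
    "exclude_hyper_doublets",
    "robustness_fisher",
    "permutation_burden_test",
]

FLAG_HYPER_EXCLUDED = "hyper_excluded"


@dataclass
class BurdenProfile:
    counts: dict[str, int]
    Q3: float
    IQR: float
    threshold: float
    hyper_flags: dict[str, bool]

    @property
    def hyper_samples(self) -> set[str]:
        return {s for s, f in self.hyper_flags.items() if f}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"sample_id": s, "count": c, "hyper": self.hyper_flags[s], "threshold": self.threshold}
                for s, c in sorted(self.counts.items())
            ]
        )


@dataclass(frozen=True)
class PermutationResult:
    observed_stat: float
    B: int
    N_exceed: int
    p_value: float
    p_value_add_one: float
    seed: int

    def __post_init__(self) -> None:
        # p is exactly N_exceed / B (up to float representation)
        assert round(self.p_value * self.B) == self.N_exceed
        assert abs(self.p_value * self.B - self.N_exceed) < 1e-6


def mutation_counts(cohort: Cohort) -> dict[str, int]:
    """Per-sample count of retained (non-synonymous) mutation records."""
    return cohort.df.groupby("sample_id").size().to_dict()


def flag_hypermutated(counts: dict[str, int], k: float = 8.0) -> BurdenProfile:
    """Flag samples whose count strictly exceeds Q3 + k x IQR.

    Quartiles are linearly interpolated between order statistics at
    probability positions p*(n-1).  Requires at least 4 samples.
    """
    if len(counts) < 4:
        raise ValueError("insufficient samples for quartiles (need >= 4)")
    values = np.asarray(list(counts.values()), dtype=float)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    threshold = q3 + k * iqr
    return BurdenProfile(
        counts=dict(counts),
        Q3=float(q3),
        IQR=float(iqr),
        threshold=float(threshold),
        hyper_flags={s: c > threshold for s, c in counts.items()},
    )


def exclude_hyper_doublets(
    doublets: list[Doublet],
    profile: BurdenProfile,
    mode: str = "any_carrier",
) -> tuple[list[Doublet], list[Doublet]]:
    """Partition doublets into (excluded, retained) by hyper-mutated carriage.

    Under ``any_carrier`` (default) one hyper-mutated carrier suffices for
    exclusion; under ``all_carriers`` every carrier must be hyper-mutated.
    """
    if mode not in ("any_carrier", "all_carriers"):
        raise ValueError(f"unknown mode {mode!r}")
    hyper = profile.hyper_samples
    excluded, retained = [], []
    for d in doublets:
        carriers = d.carriers
        hit = bool(carriers & hyper) if mode == "any_carrier" else bool(carriers) and carriers <= hyper
        if hit:
            d.filter_flags.add(FLAG_HYPER_EXCLUDED)
            excluded.append(d)
        else:
            retained.append(d)
    return excluded, retained


def robustness_fisher(
    doublet: Doublet,
    non_hyper_samples: set[str],
    non_hyper_n: int,
    alpha: float = 0.05,
) -> dict:
    """Re-test a doublet in the non-hyper-mutated cohort.

    The contingency table is rebuilt over the surviving samples with their
    own N; significance is a strict p < alpha on the two-sided Fisher test.
    """
    ci = doublet.pm_i.carriers & non_hyper_samples
    cj = doublet.pm_j.carriers & non_hyper_samples
    a = len(ci & cj)
    b = len(ci - cj)
    c = len(cj - ci)
    d = non_hyper_n - (a + b + c)
    table = ContingencyTable(a, b, c, d)
    p = float(fisher_exact(table.as_list(), alternative="two-sided")[1])
    note = "" if a > 0 else "no carriers left in non-hyper-mutated cohort"
    return {
        "gene": doublet.gene,
        "pos_i": doublet.pos_i,
        "pos_j": doublet.pos_j,
        "a": a,
        "b": b,
        "c": c,
        "d": d,
        "p": p,
        "significant": bool(p < alpha) and a > 0,
        "note": note,
    }


def permutation_burden_test(
    double_counts: list[float],
    single_counts: list[float],
    B: int = 5000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of mean(Double) - mean(Single) on mutation burdens.

    The null hypothesis is that double-mutant tumors carry a burden no higher
    than the remaining gene-mutant tumors; reject when p < 0.01.
    """
    if not double_counts or not single_counts:
        raise ValueError("both groups must be nonempty")
    rng = np.random.default_rng(seed)
    dbl = np.asarray(double_counts, dtype=float)
    sgl = np.asarray(single_counts, dtype=float)
    pooled = np.concatenate([dbl, sgl])
    n_d = dbl.size
    observed = dbl.mean() - sgl.mean()

    # vectorised label shuffles: one permutation of the pooled vector per row
    idx = np.argsort(rng.random((B, pooled.size)), axis=1)
    perm = pooled[idx]
    stats = perm[:, :n_d].mean(axis=1) - perm[:, n_d:].mean(axis=1)
    n_exceed = int(np.sum(stats > observed))
    return PermutationResult(
        observed_stat=float(observed),
        B=B,
        N_exceed=n_exceed,
        p_value=n_exceed / B,
        p_value_add_one=(n_exceed + 1) / (B + 1),
        seed=seed,
    )
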