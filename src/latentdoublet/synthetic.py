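"""Seeded synthetic cohort generator.

Emulates the statistical structure of a multi-tissue pan-cancer somatic
mutation cohort at desk scale: per-sample background mutation loads drawn
from a negative-binomial (heavy-tailed burden), a hyper-mutator subpopulation
with inflated load, Beta-distributed variant allele frequencies, a
missense/nonsense/frameshift class mixture, uniform trinucleotide contexts,
and *planted* same-gene doublets with exactly specified joint and marginal
carrier counts.  Companion generators emit a matching driver catalog,
cell-line drug-response z-score tables and PDX tumor-volume time courses.

Everything is deterministic for a fixed seed, and a TruthTable records the
planted structure so downstream discovery can be scored against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .maf_io import CANONICAL_COLUMNS, Cohort
from .sbs import enumerate_contexts

__all__ = [
    "PlantedDoublet",
    "SimulationConfig",
    "TruthTable",
    "generate_cohort",
    "generate_driver_catalog",
    "generate_preclinical",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PlantedDoublet:
    """A same-gene mutation pair planted with fixed contingency structure.

    ``joint`` samples carry both positions; ``marginal_i``/``marginal_j`` are
    the total carrier counts of each component (joint included).  Components
    are missense so they survive the nonsense filters; ``context`` forces a
    shared trinucleotide context on both components (context-biased mode).
    """

    gene: str
    pos_i: int
    pos_j: int
    joint: int
    marginal_i: int
    marginal_j: int
    driver_i: bool = False
    driver_j: bool = False
    context: str | None = None


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 2000
    n_genes: int = 50
    positions_per_gene: int = 40
    background_rate: float = 3.0  # mean background mutations per sample
    background_dispersion: float = 1.0  # NB size parameter; smaller = heavier tail
    planted_doublets: tuple[PlantedDoublet, ...] = ()
    vaf_beta: tuple[float, float] = (2.0, 2.0)
    hyper_fraction: float = 0.0
    hyper_multiplier: float = 10.0
    class_mix: tuple[tuple[str, float], ...] = (
        ("missense", 0.80),
        ("nonsense", 0.12),
        ("frameshift", 0.08),
    )
    n_tissues: int = 5
    seed: int = 0

    def validate(self) -> None:
        probs = [p for _, p in self.class_mix]
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("class_mix probabilities must sum to 1")
        for pd_ in self.planted_doublets:
            if pd_.pos_i == pd_.pos_j:
                raise ValueError("planted doublet positions must differ")
            if not (pd_.joint <= pd_.marginal_i <= self.n_samples):
                raise ValueError(f"infeasible planted counts for {pd_.gene}: marginal_i")
            if not (pd_.joint <= pd_.marginal_j <= self.n_samples):
                raise ValueError(f"infeasible planted counts for {pd_.gene}: marginal_j")
            if pd_.marginal_i + pd_.marginal_j - pd_.joint > self.n_samples:
                raise ValueError(f"infeasible planted counts for {pd_.gene}: union exceeds cohort")


@dataclass
class TruthTable:
    """Ground truth of a simulated cohort."""

    planted: list[dict] = field(default_factory=list)
    hyper_samples: list[str] = field(default_factory=list)
    driver_mutations: list[dict] = field(default_factory=list)  # gene, position
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        return cls(**json.loads(Path(path).read_text()))


def _draw_vaf_depth(rng: np.random.Generator, n: int, beta: tuple[float, float]):
    vaf = rng.beta(*beta, size=n)
    depth = rng.integers(50, 201, size=n)
    alt = np.clip(np.rint(vaf * depth), 1, depth).astype(int)
    return alt, depth


def generate_cohort(config: SimulationConfig) -> tuple[Cohort, TruthTable]:
    """Generate a seeded cohort plus its truth table.

    Planted doublets appear with exactly the configured joint/marginal
    carrier counts (background mutations never hit planted positions, so the
    emitted contingency counts match the configuration exactly).  Background
    mutations are assigned independently across samples.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    width = max(5, len(str(n)))
    samples = [f"S{idx:0{width}d}" for idx in range(n)]
    tissues = [f"tissue_{t}" for t in rng.integers(0, config.n_tissues, size=n)]
    subtypes = [f"subtype_{t}" for t in rng.integers(0, 3 * config.n_tissues, size=n)]

    n_hyper = int(round(config.hyper_fraction * n))
    hyper_idx = set(rng.choice(n, size=n_hyper, replace=False)) if n_hyper else set()

    contexts = enumerate_contexts()
    planted_positions = {
        (p.gene, pos) for p in config.planted_doublets for pos in (p.pos_i, p.pos_j)
    }
    # background pool excludes planted positions so truth counts stay exact
    pool = [
        (f"GENE{g:03d}", pos)
        for g in range(config.n_genes)
        for pos in range(1, config.positions_per_gene + 1)
        if (f"GENE{g:03d}", pos) not in planted_positions
    ]
    class_names = [c for c, _ in config.class_mix]
    class_probs = [p for _, p in config.class_mix]

    rows: list[dict] = []

    def emit(sample_idx: int, gene: str, pos: int, vclass: str, ctx: str) -> None:
        vaf_alt, vaf_depth = _draw_vaf_depth(rng, 1, config.vaf_beta)
        alt, depth = int(vaf_alt[0]), int(vaf_depth[0])
        ref = _AA[rng.integers(0, 20)]
        if vclass == "nonsense":
            alt_aa = "*"
        elif vclass == "frameshift":
            alt_aa = "fs"
        else:
            alt_aa = _AA[rng.integers(0, 20)]
            while alt_aa == ref:
                alt_aa = _AA[rng.integers(0, 20)]
        rows.append(
            {
                "sample_id": samples[sample_idx],
                "patient_id": samples[sample_idx],
                "gene": gene,
                "protein_position": pos,
                "ref_aa": ref,
                "alt_aa": alt_aa,
                "variant_class": vclass,
                "t_alt_count": alt,
                "t_depth": depth,
                "vaf": alt / depth,
                "tissue": tissues[sample_idx],
                "subtype": subtypes[sample_idx],
                "context": ctx,
                "sample_type": "primary",
                "multi_position": False,
            }
        )

    # background load
    r = config.background_dispersion
    for i in range(n):
        mean = config.background_rate * (config.hyper_multiplier if i in hyper_idx else 1.0)
        count = int(rng.negative_binomial(r, r / (r + mean)))
        count = min(count, len(pool))
        if count == 0:
            continue
        for j in rng.choice(len(pool), size=count, replace=False):
            gene, pos = pool[j]
            vclass = class_names[rng.choice(len(class_names), p=class_probs)]
            emit(i, gene, pos, vclass, contexts[rng.integers(0, len(contexts))])

    # planted doublets
    truth = TruthTable(seed=config.seed, hyper_samples=sorted(samples[i] for i in hyper_idx))
    for p in config.planted_doublets:
        total = p.marginal_i + p.marginal_j - p.joint
        chosen = rng.choice(n, size=total, replace=False)
        joint_s = chosen[: p.joint]
        only_i = chosen[p.joint : p.marginal_i]
        only_j = chosen[p.marginal_i :]
        ctx_i = p.context or contexts[rng.integers(0, len(contexts))]
        ctx_j = p.context or contexts[rng.integers(0, len(contexts))]
        for i in np.concatenate([joint_s, only_i]):
            emit(int(i), p.gene, p.pos_i, "missense", ctx_i)
        for i in np.concatenate([joint_s, only_j]):
            emit(int(i), p.gene, p.pos_j, "missense", ctx_j)
        truth.planted.append(
            {
                "gene": p.gene,
                "pos_i": p.pos_i,
                "pos_j": p.pos_j,
                "a": p.joint,
                "b": p.marginal_i - p.joint,
                "c": p.marginal_j - p.joint,
                "d": n - total,
                "carriers_both": sorted(samples[int(i)] for i in joint_s),
            }
        )
        if p.driver_i:
            truth.driver_mutations.append({"gene": p.gene, "position": p.pos_i})
        if p.driver_j:
            truth.driver_mutations.append({"gene": p.gene, "position": p.pos_j})

    df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS + ["multi_position"])
    df = df.sort_values(["sample_id", "gene", "protein_position"], kind="mergesort").reset_index(drop=True)
    return Cohort(df), truth


def generate_driver_catalog(truth: TruthTable) -> pd.DataFrame:
    """Catalog table of the truth's known-driver mutations (gene, protein_position)."""
    return pd.DataFrame(
        [{"gene": m["gene"], "protein_position": m["position"]} for m in truth.driver_mutations],
        columns=["gene", "protein_position"],
    )


def generate_preclinical(
    truth: TruthTable,
    seed: int = 0,
    n_drugs: int = 10,
    sensitive_offsets: dict[tuple[str, str], float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Matching preclinical tables for the first planted doublet.

    Returns (cell-line mutation table, drug z-score table, PDX growth table).
    Cell lines: one double-mutant line carrying both components and one
    single-mutant line per component.  Z-scores are standard normal except
    for configured (cell_line, drug) offsets (default: the double-mutant line
    is strongly sensitive, offset -4, to DRUG_000).  PDX volume curves use
    irregular timepoints including non-multiples of 5.
    """
    rng = np.random.default_rng(seed)
    drugs = [f"DRUG_{k:03d}" for k in range(n_drugs)]

    lines_rows = []
    if truth.planted:
        p = truth.planted[0]
        lines_rows = [
            {"cell_line": "LINE_DOUBLE", "gene": p["gene"], "protein_position": p["pos_i"]},
            {"cell_line": "LINE_DOUBLE", "gene": p["gene"], "protein_position": p["pos_j"]},
            {"cell_line": "LINE_SINGLE_I", "gene": p["gene"], "protein_position": p["pos_i"]},
            {"cell_line": "LINE_SINGLE_J", "gene": p["gene"], "protein_position": p["pos_j"]},
        ]
    lines_df = pd.DataFrame(lines_rows, columns=["cell_line", "gene", "protein_position"])

    if sensitive_offsets is None:
        sensitive_offsets = {("LINE_DOUBLE", "DRUG_000"): -4.0}
    z_rows = []
    for line in ["LINE_DOUBLE", "LINE_SINGLE_I", "LINE_SINGLE_J"]:
        for drug in drugs:
            z = float(np.clip(rng.normal(0.0, 1.0), -1.9, 1.9))
            z += sensitive_offsets.get((line, drug), 0.0)
            z_rows.append({"cell_line": line, "drug": drug, "z_score": z})
    z_df = pd.DataFrame(z_rows, columns=["cell_line", "drug", "z_score"])

    # PDX growth: irregular timepoints (non-multiples of 5 included);
    # untreated grows, treated double-mutant shrinks
    timepoints = [0, 3, 7, 10, 14]
    pdx_rows = []
    for model, treatment, slope in [
        ("PDX_DOUBLE", "untreated", 170.0),
        ("PDX_DOUBLE", "treated", -20.0),
        ("PDX_SINGLE", "untreated", 80.0),
        ("PDX_SINGLE", "treated", 30.0),
    ]:
        v0 = 100.0
        for t in timepoints:
            vol = max(v0 + slope * t + rng.normal(0.0, 5.0), 1.0)
            pdx_rows.append(
                {
                    "model": model,
                    "treatment": treatment,
                    "timepoint_days": t,
                    "volume_mm3": round(vol, 2),
                }
            )
    pdx_df = pd.DataFrame(pdx_rows, columns=["model", "treatment", "timepoint_days", "volume_mm3"])
    return lines_df, z_df, pdx_df
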