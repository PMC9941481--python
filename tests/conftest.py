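from __future__ import annotations

import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from latentdoublet.discovery import PositionMutation
from latentdoublet.maf_io import CANONICAL_COLUMNS, Cohort


def make_cohort(rows: list[dict]) -> Cohort:
    """Build a cohort frame from sparse row dicts, filling sensible defaults."""
    full = []
    for r in rows:
        depth = r.get("t_depth", 100)
        alt = r.get("t_alt_count", int(round(r.get("vaf", 0.4) * depth)))
        base = {
            "sample_id": "S1",
            "patient_id": r.get("sample_id", "S1"),
            "gene": "GENE",
            "protein_position": 1,
            "ref_aa": "E",
            "alt_aa": "K",
            "variant_class": "missense",
            "t_alt_count": alt,
            "t_depth": depth,
            "vaf": alt / depth,
            "tissue": "lung",
            "subtype": "LUAD",
            "context": None,
            "sample_type": "primary",
            "multi_position": False,
        }
        base.update({k: v for k, v in r.items() if k not in ("vaf",)})
        base["vaf"] = base["t_alt_count"] / base["t_depth"]
        full.append(base)
    return Cohort(pd.DataFrame(full, columns=CANONICAL_COLUMNS + ["multi_position"]))


def make_pm(
    gene: str = "GENE",
    position: int = 1,
    carriers: dict[str, tuple[str, float]] | None = None,
    contexts: dict[str, str] | None = None,
) -> PositionMutation:
    """PositionMutation from {sample: (variant_class, vaf)}."""
    carriers = carriers or {"S1": ("missense", 0.4)}
    return PositionMutation(
        gene=gene,
        position=position,
        carriers=frozenset(carriers),
        class_by_carrier={s: c for s, (c, _) in carriers.items()},
        vaf_by_carrier={s: v for s, (_, v) in carriers.items()},
        context_by_carrier=dict(contexts or {}),
    )


@pytest.fixture
def tiny_maf(tmp_path) -> Path:
    """A small standard-dialect MAF file on disk."""
    rows = [
        # barcode, gene, pchange, class, alt, depth, tissue, stype
        ("T-01", "PIK3CA", "p.E545K", "Missense_Mutation", 40, 100, "breast", "primary"),
        ("T-01", "PIK3CA", "p.E726K", "Missense_Mutation", 35, 100, "breast", "primary"),
        ("T-02", "PIK3CA", "p.E545K", "Missense_Mutation", 5, 20, "breast", "primary"),
        ("T-03", "TP53", "p.R175H", "Missense_Mutation", 30, 100, "lung", "primary"),
        ("T-03", "TP53", "p.R213*", "Nonsense_Mutation", 28, 100, "lung", "primary"),
        ("T-04", "TP53", "p.R175H", "Silent", 50, 100, "lung", "primary"),
        ("T-05", "KRAS", "p.G12D", "Missense_Mutation", 10, 100, "bowel", "primary"),  # vaf 0.10
        ("T-06", "KRAS", "p.G12_G13fs", "Frame_Shift_Del", 40, 100, "bowel", "primary"),
    ]
    lines = ["\t".join([
        "Tumor_Sample_Barcode", "Hugo_Symbol", "HGVSp_Short", "Variant_Classification",
        "t_alt_count", "t_depth", "Tissue", "Sample_Type",
    ])]
    for r in rows:
        lines.append("\t".join(str(x) for x in r))
    path = tmp_path / "tiny.maf.tsv"
    path.write_text("\n".join(lines) + "\n")
    return path
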