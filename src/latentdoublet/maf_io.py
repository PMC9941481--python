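"""Reading, validating, filtering and writing MAF-style somatic mutation tables.

A cohort is held as a pandas DataFrame with one row per sample-level mutation
and a canonical column set (see :data:`CANONICAL_COLUMNS`).  The variant allele
frequency (VAF) of every record is ``t_alt_count / t_depth``; under the usual
heterozygous-diploid assumption a VAF of 0.125 corresponds to roughly 25% of
the sequenced cells carrying the mutation, which motivates the default
filtering threshold.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "NONSYNONYMOUS_CLASSES",
    "Cohort",
    "MutationRecord",
    "SkipReport",
    "load_maf",
    "filter_cohort",
    "dedup_patients",
    "write_maf",
]

#: Canonical internal column names, in output order.
CANONICAL_COLUMNS = [
    "sample_id",
    "patient_id",
    "gene",
    "protein_position",
    "ref_aa",
    "alt_aa",
    "variant_class",
    "t_alt_count",
    "t_depth",
    "vaf",
    "tissue",
    "subtype",
    "context",
    "sample_type",
]

#: Retained variant classes; everything else (silent, splice, UTR...) is
#: dropped by :func:`filter_cohort`.
NONSYNONYMOUS_CLASSES = frozenset({"missense", "nonsense", "nonstop", "frameshift"})

#: Standard MAF column dialect -> canonical names.  A user ``column_map``
#: overrides / extends these.
_DEFAULT_COLUMN_MAP: dict[str, str] = {
    "Tumor_Sample_Barcode": "sample_id",
    "Patient_ID": "patient_id",
    "Hugo_Symbol": "gene",
    "Protein_position": "protein_position",
    "Reference_AA": "ref_aa",
    "Mutant_AA": "alt_aa",
    "Variant_Classification": "variant_class",
    "t_alt_count": "t_alt_count",
    "t_depth": "t_depth",
    "Tissue": "tissue",
    "Oncotree_Code": "subtype",
    "Trinucleotide_Context": "context",
    "Sample_Type": "sample_type",
    "HGVSp_Short": "protein_change",
    "Protein_Change": "protein_change",
}

#: MAF Variant_Classification values -> canonical class enum.
_CLASS_MAP = {
    "missense_mutation": "missense",
    "missense": "missense",
    "nonsense_mutation": "nonsense",
    "nonsense": "nonsense",
    "nonstop_mutation": "nonstop",
    "nonstop": "nonstop",
    "frame_shift_ins": "frameshift",
    "frame_shift_del": "frameshift",
    "frameshift": "frameshift",
    "silent": "silent",
    "synonymous": "silent",
}

_REQUIRED = ["sample_id", "gene", "protein_position", "variant_class", "t_alt_count", "t_depth"]

# p.E545K / p.R130* / p.K467fs / E545K ; group residue, position, alt
_PCHANGE_RE = re.compile(r"^p?\.?([A-Z*])(\d+)(?:_[A-Z]?(\d+))?(.*)$")

_SAMPLE_TYPE_PRIORITY = {"primary": 0, "metastatic": 1, "unspecified": 2}


class ColumnConfigurationError(ValueError):
    """A required input column could not be resolved."""


@dataclass(frozen=True)
class MutationRecord:
    """One sample-level somatic mutation."""

    sample_id: str
    patient_id: str
    gene: str
    protein_position: int
    ref_aa: str
    alt_aa: str
    variant_class: str
    t_alt_count: int
    t_depth: int
    vaf: float
    tissue: str = ""
    subtype: str = ""
    context: str | None = None
    sample_type: str = "unspecified"

    def __post_init__(self) -> None:
        if self.t_depth < 1:
            raise ValueError("t_depth must be >= 1")
        if self.t_alt_count > self.t_depth:
            raise ValueError("t_alt_count exceeds t_depth")
        if abs(self.vaf - self.t_alt_count / self.t_depth) > 1e-12:
            raise ValueError("vaf inconsistent with t_alt_count / t_depth")


@dataclass
class SkipReport:
    """Rows rejected during load, with a reason each."""

    rows: list[tuple[int, str]] = field(default_factory=list)

    def add(self, row: int, reason: str) -> None:
        self.rows.append((row, reason))

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["row", "reason"])


@dataclass
class Cohort:
    """A collection of somatic mutation records across tumor samples.

    ``N`` is the number of distinct samples with at least one retained
    mutation; it is the total of every 2x2 contingency table built downstream
    (``d = N - (a + b + c)``).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ColumnConfigurationError(f"cohort frame missing columns: {missing}")

    @property
    def N(self) -> int:
        return int(self.df["sample_id"].nunique())

    @property
    def samples(self) -> set[str]:
        return set(self.df["sample_id"].unique())

    @property
    def tissue_of(self) -> dict[str, str]:
        return self.df.drop_duplicates("sample_id").set_index("sample_id")["tissue"].to_dict()

    @property
    def subtype_of(self) -> dict[str, str]:
        return self.df.drop_duplicates("sample_id").set_index("sample_id")["subtype"].to_dict()

    def records(self) -> list[MutationRecord]:
        cols = [f.name for f in MutationRecord.__dataclass_fields__.values()]  # type: ignore[attr-defined]
        out = []
        for row in self.df[cols].itertuples(index=False):
            d = row._asdict()
            if pd.isna(d.get("context")):
                d["context"] = None
            out.append(MutationRecord(**d))
        return out

    def __len__(self) -> int:
        return len(self.df)


def _parse_protein_change(change: str) -> tuple[str, int, int | None, str] | None:
    """Parse a p.X123Y-style string into (ref, pos, end_pos_or_None, alt tail)."""
    if not isinstance(change, str) or not change:
        return None
    m = _PCHANGE_RE.match(change.strip())
    if not m:
        return None
    ref, pos, end, tail = m.group(1), int(m.group(2)), m.group(3), m.group(4)
    return ref, pos, (int(end) if end else None), tail


def load_maf(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[Cohort, SkipReport]:
    """Load a tab-delimited MAF-style mutation table.

    Parameters
    ----------
    path
        Tab-delimited file with a header row.  Standard MAF column names are
        recognised out of the box; ``column_map`` maps additional dialect
        names onto canonical ones (``{"my_barcode_col": "sample_id", ...}``).

    Returns
    -------
    cohort, skip_report
        Rows with unparseable required fields are skipped and reported with a
        reason; row order does not affect the resulting cohort content.
    """
    cmap = dict(_DEFAULT_COLUMN_MAP)
    # canonical names pass through
    for c in CANONICAL_COLUMNS + ["protein_change"]:
        cmap.setdefault(c, c)
    if column_map:
        cmap.update(column_map)

    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    raw = raw.rename(columns={k: v for k, v in cmap.items() if k in raw.columns})
    # resolve duplicate targets (e.g. HGVSp_Short and Protein_Change both map
    # to protein_change) by keeping the first occurrence
    raw = raw.loc[:, ~raw.columns.duplicated()]

    have_pchange = "protein_change" in raw.columns
    for col in _REQUIRED:
        if col not in raw.columns:
            if col == "protein_position" and have_pchange:
                continue
            raise ColumnConfigurationError(f"required column not found: {col!r}")

    skip = SkipReport()
    rows: list[dict] = []
    for i, rec in enumerate(raw.to_dict("records")):
        gene = rec.get("gene")
        sample = rec.get("sample_id")
        if not isinstance(gene, str) or not gene:
            skip.add(i, "missing gene")
            continue
        if not isinstance(sample, str) or not sample:
            skip.add(i, "missing sample barcode")
            continue
        try:
            alt = int(float(rec["t_alt_count"]))
            depth = int(float(rec["t_depth"]))
        except (ValueError, TypeError, KeyError):
            skip.add(i, "unparseable read counts")
            continue
        if depth == 0:
            skip.add(i, "zero depth")
            continue
        if alt < 0 or alt > depth:
            skip.add(i, "t_alt_count outside [0, t_depth]")
            continue

        vclass = _CLASS_MAP.get(str(rec.get("variant_class", "")).lower(), "other")

        ref_aa = rec.get("ref_aa")
        alt_aa = rec.get("alt_aa")
        pos = rec.get("protein_position")
        end_pos = None
        parsed = _parse_protein_change(rec.get("protein_change", "")) if have_pchange else None
        if parsed is not None:
            p_ref, p_pos, p_end, p_tail = parsed
            if not isinstance(ref_aa, str) or not ref_aa:
                ref_aa = p_ref
            if not isinstance(alt_aa, str) or not alt_aa:
                alt_aa = p_tail or None
            if pos is None or (isinstance(pos, float) and pd.isna(pos)):
                pos = p_pos
            end_pos = p_end
        try:
            pos = int(float(pos))
        except (ValueError, TypeError):
            skip.add(i, "unparseable protein position")
            continue
        if pos < 1:
            skip.add(i, "protein position < 1")
            continue
        multi_position = end_pos is not None and end_pos != pos
        if str(rec.get("multi_position", "")).lower() == "true":
            multi_position = True

        rows.append(
            {
                "sample_id": sample,
                "patient_id": rec.get("patient_id") if isinstance(rec.get("patient_id"), str) else sample,
                "gene": gene,
                "protein_position": pos,
                "ref_aa": ref_aa if isinstance(ref_aa, str) else "",
                "alt_aa": alt_aa if isinstance(alt_aa, str) else "",
                "variant_class": vclass,
                "t_alt_count": alt,
                "t_depth": depth,
                "vaf": alt / depth,
                "tissue": rec.get("tissue") if isinstance(rec.get("tissue"), str) else "",
                "subtype": rec.get("subtype") if isinstance(rec.get("subtype"), str) else "",
                "context": rec.get("context") if isinstance(rec.get("context"), str) else None,
                "sample_type": (
                    rec.get("sample_type").lower()
                    if isinstance(rec.get("sample_type"), str)
                    else "unspecified"
                ),
                "multi_position": multi_position,
            }
        )

    df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS + ["multi_position"])
    df = df.sort_values(["sample_id", "gene", "protein_position"], kind="mergesort").reset_index(drop=True)
    return Cohort(df), skip


def filter_cohort(cohort: Cohort, vaf_min: float = 0.125) -> Cohort:
    """Retain non-synonymous single-position mutations with VAF strictly above ``vaf_min``.

    Keeps classes missense / nonsense / nonstop / single-position frameshift,
    drops records whose wild-type or mutant residue is unspecified, and drops
    frameshifts annotated as spanning more than one residue.  ``N`` is
    recomputed over the surviving samples.
    """
    if not (0 < vaf_min < 1):
        raise ValueError(f"vaf_min must lie in (0, 1); got {vaf_min}")
    df = cohort.df
    keep = (
        df["variant_class"].isin(NONSYNONYMOUS_CLASSES)
        & (df["vaf"] > vaf_min)
        & df["ref_aa"].astype(bool)
        & df["alt_aa"].astype(bool)
    )
    if "multi_position" in df.columns:
        keep &= ~df["multi_position"].fillna(False).astype(bool)
    return Cohort(df.loc[keep].reset_index(drop=True))


def dedup_patients(cohort: Cohort) -> Cohort:
    """Keep exactly one tumor sample per patient.

    Priority: primary > metastatic > unspecified; within a tier, the
    lexicographically smallest barcode is kept (deterministic tie-break).
    """
    df = cohort.df
    per_sample = df[["patient_id", "sample_id", "sample_type"]].drop_duplicates("sample_id").copy()
    per_sample["prio"] = per_sample["sample_type"].map(_SAMPLE_TYPE_PRIORITY).fillna(2).astype(int)
    per_sample = per_sample.sort_values(["patient_id", "prio", "sample_id"], kind="mergesort")
    keep_samples = set(per_sample.drop_duplicates("patient_id")["sample_id"])
    return Cohort(df[df["sample_id"].isin(keep_samples)].reset_index(drop=True))


def write_maf(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort back to MAF-style TSV with canonical column names."""
    cols = CANONICAL_COLUMNS + (["multi_position"] if "multi_position" in cohort.df.columns else [])
    cohort.df[cols].to_csv(path, sep="\t", index=False)
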