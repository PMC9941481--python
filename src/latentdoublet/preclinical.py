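"""Cell-line drug-response rules and PDX growth-curve comparison.

Drug-response z-scores are called sensitive (z < -2), resistant (z > 2) or
gray (|z| <= 2); more negative means more sensitive.  Two selection schemes
compare single-mutant against double-mutant cell lines:

* ``gray_to_significant_or_flip`` — the drug is gray in every single-mutant
  line but significant in the double-mutant line, or the double-mutant call
  flips the sign of a significant single-mutant call;
* ``significant_in_either`` — any line, single or double, is significant.

Xenograft tumor-volume time courses are aligned to a 5-day grid by linear
interpolation between the nearest bracketing observations,

    Vol_i = Vol_{i-1} + (t_i - t_{i-1}) / (t_{i+1} - t_{i-1}) * (Vol_{i+1} - Vol_{i-1}),

with no extrapolation beyond the observed range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DrugResponse",
    "GrowthCurve",
    "call_response",
    "select_drugs",
    "build_network",
    "network_edge_list",
    "interpolate_volume",
    "volume_change",
]


@dataclass(frozen=True)
class DrugResponse:
    cell_line: str
    drug: str
    z_score: float

    @property
    def call(self) -> str:
        return call_response(self.z_score)


@dataclass(frozen=True)
class GrowthCurve:
    model_id: str
    treatment: str
    timepoints: tuple[int, ...]
    volumes: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.timepoints) != len(self.volumes) or len(self.timepoints) < 2:
            raise ValueError("need matching timepoints/volumes with at least 2 observations")
        if any(t2 <= t1 for t1, t2 in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if any(t < 0 for t in self.timepoints) or any(v < 0 for v in self.volumes):
            raise ValueError("timepoints and volumes must be nonnegative")

    def volume_at(self, day: int) -> float:
        if day not in self.timepoints:
            raise ValueError(f"day {day} not on the curve grid")
        return self.volumes[self.timepoints.index(day)]


def call_response(z_score: float, z_cut: float = 2.0) -> str:
    """Sensitive / resistant / gray call for a drug-response z-score.

    The boundary |z| == z_cut is gray (non-significant).
    """
    if not math.isfinite(z_score):
        raise ValueError("z-score must be finite")
    if z_score < -z_cut:
        return "sensitive"
    if z_score > z_cut:
        return "resistant"
    return "gray"


def select_drugs(
    double_line_responses: list[DrugResponse],
    single_line_responses: list[DrugResponse],
    scheme: str = "gray_to_significant_or_flip",
    z_cut: float = 2.0,
) -> pd.DataFrame:
    """Select drugs distinguishing double-mutant from single-mutant cell lines.

    Returns one row per selected (double-mutant line, drug) with the rule that
    triggered the selection.  Drugs absent from one side are skipped with a
    note row (rule "missing_counterpart") under scheme 1.
    """
    if scheme not in ("gray_to_significant_or_flip", "significant_in_either"):
        raise ValueError(f"unknown scheme {scheme!r}")
    singles_by_drug: dict[str, list[DrugResponse]] = {}
    for r in single_line_responses:
        singles_by_drug.setdefault(r.drug, []).append(r)

    rows = []
    for r in double_line_responses:
        call_d = call_response(r.z_score, z_cut)
        singles = singles_by_drug.get(r.drug)
        if scheme == "significant_in_either":
            single_signif = any(
                call_response(s.z_score, z_cut) != "gray" for s in (singles or [])
            )
            if call_d != "gray" or single_signif:
                rows.append(
                    {
                        "cell_line": r.cell_line,
                        "drug": r.drug,
                        "z_double": r.z_score,
                        "call_double": call_d,
                        "rule": "significant_in_either",
                    }
                )
            continue
        if singles is None:
            rows.append(
                {
                    "cell_line": r.cell_line,
                    "drug": r.drug,
                    "z_double": r.z_score,
                    "call_double": call_d,
                    "rule": "missing_counterpart",
                }
            )
            continue
        single_calls = [call_response(s.z_score, z_cut) for s in singles]
        all_gray = all(c == "gray" for c in single_calls)
        if all_gray and call_d != "gray":
            rows.append(
                {
                    "cell_line": r.cell_line,
                    "drug": r.drug,
                    "z_double": r.z_score,
                    "call_double": call_d,
                    "rule": "gray_to_significant",
                }
            )
        elif call_d != "gray" and any(
            c in ("sensitive", "resistant") and c != call_d for c in single_calls
        ):
            rows.append(
                {
                    "cell_line": r.cell_line,
                    "drug": r.drug,
                    "z_double": r.z_score,
                    "call_double": call_d,
                    "rule": "flip",
                }
            )
    return pd.DataFrame(
        rows, columns=["cell_line", "drug", "z_double", "call_double", "rule"]
    )


def build_network(
    selections: pd.DataFrame,
    mutations_of_lines: dict[str, list[str]],
    targets_of_drugs: dict[str, list[str]] | None = None,
    pathways_of_drugs: dict[str, str] | None = None,
) -> nx.Graph:
    """Assemble the mutation-cellline-drug-pathway graph.

    Node types: mutation, cell_line, drug, pathway.  Edge types: harbors
    (cell line -> mutation), sensitive/resistant (cell line -> drug, from the
    selection call), targets (drug -> pathway).
    """
    g = nx.Graph()
    for line, muts in mutations_of_lines.items():
        g.add_node(line, node_type="cell_line")
        for m in muts:
            g.add_node(m, node_type="mutation")
            g.add_edge(line, m, edge_type="harbors")
    selected_rows = selections[selections["rule"] != "missing_counterpart"]
    for row in selected_rows.itertuples(index=False):
        g.add_node(row.cell_line, node_type="cell_line")
        g.add_node(row.drug, node_type="drug")
        etype = row.call_double if row.call_double in ("sensitive", "resistant") else "response"
        g.add_edge(row.cell_line, row.drug, edge_type=etype)
        for target in (targets_of_drugs or {}).get(row.drug, []):
            g.add_node(target, node_type="pathway")
            g.add_edge(row.drug, target, edge_type="targets")
        pathway = (pathways_of_drugs or {}).get(row.drug)
        if pathway:
            g.add_node(pathway, node_type="pathway")
            g.add_edge(row.drug, pathway, edge_type="targets")
    return g


def network_edge_list(g: nx.Graph) -> pd.DataFrame:
    """Typed edge list for serialisation."""
    rows = [
        {
            "source": u,
            "source_type": g.nodes[u].get("node_type", ""),
            "target": v,
            "target_type": g.nodes[v].get("node_type", ""),
            "edge_type": data.get("edge_type", ""),
        }
        for u, v, data in sorted(g.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["source", "source_type", "target", "target_type", "edge_type"])


def interpolate_volume(curve: GrowthCurve, grid_step: int = 5) -> GrowthCurve:
    """Resample a growth curve onto multiples of ``grid_step`` days.

    Observed timepoints already on the grid pass through unchanged; other
    grid points are linearly interpolated between the nearest bracketing
    observations.  Grid points outside the observed range are omitted (no
    extrapolation).
    """
    if grid_step < 1:
        raise ValueError("grid_step must be a positive integer")
    t = np.asarray(curve.timepoints, dtype=float)
    v = np.asarray(curve.volumes, dtype=float)
    lo = int(math.ceil(t[0] / grid_step)) * grid_step
    hi = int(math.floor(t[-1] / grid_step)) * grid_step
    grid = list(range(lo, hi + 1, grid_step))
    if not grid:
        raise ValueError("no grid points fall inside the observed time range")
    vols = np.interp(grid, t, v)
    # exact pass-through for observed on-grid points (np.interp already exact,
    # but re-assert to avoid float drift)
    for i, day in enumerate(grid):
        if day in curve.timepoints:
            vols[i] = curve.volume_at(day)
    return GrowthCurve(
        model_id=curve.model_id,
        treatment=curve.treatment,
        timepoints=tuple(grid),
        volumes=tuple(float(x) for x in vols),
    )


def volume_change(curve: GrowthCurve, t_start: int, t_end: int) -> float:
    """Volume delta (mm^3) between two days on the (interpolated) curve."""
    if t_start not in curve.timepoints or t_end not in curve.timepoints:
        raise ValueError("both days must lie on the curve grid; interpolate first")
    return curve.volume_at(t_end) - curve.volume_at(t_start)
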