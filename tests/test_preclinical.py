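import pandas as pd
import pytest

from latentdoublet.preclinical import (
    DrugResponse,
    GrowthCurve,
    build_network,
    call_response,
    interpolate_volume,
    network_edge_list,
    select_drugs,
    volume_change,
)


class TestCallResponse:
    @pytest.mark.parametrize(
        "z,expected",
        [(-3.0, "sensitive"), (-2.0, "gray"), (0.0, "gray"), (2.0, "gray"), (2.5, "resistant")],
    )
    def test_partition(self, z, expected):
        assert call_response(z) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            call_response(float("nan"))

    def test_every_finite_z_has_exactly_one_call(self):
        for z in [x / 10 for x in range(-50, 51)]:
            assert call_response(z) in ("sensitive", "resistant", "gray")


class TestSelectDrugs:
    def _resp(self, line, drug, z):
        return DrugResponse(line, drug, z)

    def test_gray_to_significant(self):
        sel = select_drugs(
            [self._resp("DBL", "d1", -3.0)], [self._resp("SGL", "d1", 1.0)]
        )
        assert len(sel) == 1 and sel.iloc[0]["rule"] == "gray_to_significant"

    def test_flip(self):
        sel = select_drugs(
            [self._resp("DBL", "d1", 2.5)], [self._resp("SGL", "d1", -3.0)]
        )
        assert len(sel) == 1 and sel.iloc[0]["rule"] == "flip"

    def test_same_direction_not_selected_scheme1_but_scheme2(self):
        dbl = [self._resp("DBL", "d1", -3.2)]
        sgl = [self._resp("SGL", "d1", -3.0)]
        assert len(select_drugs(dbl, sgl, "gray_to_significant_or_flip")) == 0
        sel2 = select_drugs(dbl, sgl, "significant_in_either")
        assert len(sel2) == 1

    def test_all_single_lines_must_be_gray(self):
        dbl = [self._resp("DBL", "d1", -3.0)]
        sgl = [self._resp("SGL1", "d1", 1.0), self._resp("SGL2", "d1", -2.5)]
        # one single line already significant-sensitive, same call -> neither rule fires
        assert len(select_drugs(dbl, sgl)) == 0

    def test_missing_counterpart_noted(self):
        sel = select_drugs([self._resp("DBL", "d9", -4.0)], [])
        assert sel.iloc[0]["rule"] == "missing_counterpart"

    def test_unknown_scheme(self):
        with pytest.raises(ValueError):
            select_drugs([], [], scheme="nope")


class TestNetwork:
    def test_counts_by_construction(self):
        selections = pd.DataFrame(
            [
                {"cell_line": "L1", "drug": "d1", "z_double": -3.0, "call_double": "sensitive", "rule": "gray_to_significant"},
                {"cell_line": "L1", "drug": "d2", "z_double": 2.6, "call_double": "resistant", "rule": "flip"},
            ]
        )
        g = build_network(
            selections,
            mutations_of_lines={"L1": ["G:10"]},
            pathways_of_drugs={"d1": "PI3K/MTOR", "d2": "RTK"},
        )
        types = {n: d["node_type"] for n, d in g.nodes(data=True)}
        assert list(types.values()).count("pathway") == 2
        edges = network_edge_list(g)
        assert (edges["edge_type"] == "harbors").sum() == 1
        assert edges["edge_type"].isin(["sensitive", "resistant"]).sum() == 2
        assert (edges["edge_type"] == "targets").sum() == 2
        # every response edge's drug is a selected drug
        resp = edges[edges["edge_type"].isin(["sensitive", "resistant"])]
        assert set(resp["target"]) | set(resp["source"]) >= set(selections["drug"])

    def test_empty_selections(self):
        g = build_network(pd.DataFrame(columns=["cell_line", "drug", "z_double", "call_double", "rule"]),
                          {"L1": ["G:10"]})
        edges = network_edge_list(g)
        assert not edges["edge_type"].isin(["sensitive", "resistant"]).any()


class TestInterpolation:
    def test_midpoint(self):
        curve = GrowthCurve("m", "untreated", (0, 10), (100.0, 200.0))
        interp = interpolate_volume(curve)
        assert interp.volume_at(5) == pytest.approx(150.0)

    def test_on_grid_passthrough(self):
        curve = GrowthCurve("m", "untreated", (0, 5, 10), (100.0, 140.0, 200.0))
        interp = interpolate_volume(curve)
        assert interp.timepoints == (0, 5, 10)
        assert interp.volumes == (100.0, 140.0, 200.0)

    def test_bracketing_pair(self):
        """(0,100),(3,130),(7,170),(10,200): day 5 from (3,130)-(7,170) -> 150."""
        curve = GrowthCurve("m", "t", (0, 3, 7, 10), (100.0, 130.0, 170.0, 200.0))
        interp = interpolate_volume(curve)
        assert interp.volume_at(5) == pytest.approx(130 + (5 - 3) / (7 - 3) * (170 - 130))

    def test_no_extrapolation(self):
        curve = GrowthCurve("m", "t", (3, 12), (100.0, 190.0))
        interp = interpolate_volume(curve)
        assert interp.timepoints == (5, 10)  # 0 and 15 are outside the observed range

    def test_interpolated_within_bracketing_volumes(self):
        curve = GrowthCurve("m", "t", (0, 3, 7, 10, 14), (100.0, 90.0, 170.0, 140.0, 200.0))
        interp = interpolate_volume(curve)
        t, v = curve.timepoints, curve.volumes
        for day, vol in zip(interp.timepoints, interp.volumes):
            k = max(i for i in range(len(t)) if t[i] <= day)
            lo, hi = (v[k], v[k]) if t[k] == day else sorted((v[k], v[k + 1]))
            assert lo - 1e-9 <= vol <= hi + 1e-9

    def test_invalid_curves(self):
        with pytest.raises(ValueError):
            GrowthCurve("m", "t", (0,), (100.0,))
        with pytest.raises(ValueError):
            GrowthCurve("m", "t", (0, 0), (100.0, 110.0))


class TestVolumeChange:
    def test_delta_and_additivity(self):
        curve = interpolate_volume(GrowthCurve("m", "t", (0, 10), (100.0, 200.0)))
        assert volume_change(curve, 0, 10) == pytest.approx(100.0)
        assert volume_change(curve, 0, 0) == 0.0
        assert volume_change(curve, 0, 10) == pytest.approx(
            volume_change(curve, 0, 5) + volume_change(curve, 5, 10)
        )

    def test_day_off_grid_errors(self):
        curve = GrowthCurve("m", "t", (0, 10), (100.0, 200.0))
        with pytest.raises(ValueError):
            volume_change(curve, 0, 7)
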