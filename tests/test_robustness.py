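import numpy as np
import pytest

from latentdoublet.discovery import ContingencyTable, Doublet
from latentdoublet.robustness import (
    exclude_hyper_doublets,
    flag_hypermutated,
    permutation_burden_test,
    robustness_fisher,
)

from conftest import make_pm
from oracles import fisher_two_sided_oracle, permutation_p_exact


class TestFlagHypermutated:
    def test_outlier_flagged_with_degenerate_iqr(self):
        counts = {f"S{i}": c for i, c in enumerate([0, 0, 0, 0, 100])}
        profile = flag_hypermutated(counts)
        assert profile.Q3 == 0 and profile.IQR == 0 and profile.threshold == 0
        assert profile.hyper_samples == {"S4"}

    def test_all_equal_none_flagged(self):
        profile = flag_hypermutated({f"S{i}": 7 for i in range(10)})
        assert profile.hyper_samples == set()  # strict inequality

    def test_interpolated_quartiles(self):
        counts = {f"S{i}": c for i, c in enumerate([1, 2, 3, 4, 5, 6, 7, 8])}
        profile = flag_hypermutated(counts)
        assert profile.Q3 == pytest.approx(6.25)
        assert profile.IQR == pytest.approx(3.5)
        assert profile.threshold == pytest.approx(34.25)
        assert profile.hyper_samples == set()

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="insufficient samples"):
            flag_hypermutated({"a": 1, "b": 2, "c": 3})

    def test_order_invariant_and_monotone(self):
        rng = np.random.default_rng(0)
        vals = rng.poisson(5, size=50)
        counts = {f"S{i}": int(v) for i, v in enumerate(vals)}
        shuffled = dict(sorted(counts.items(), key=lambda kv: -kv[1]))
        assert flag_hypermutated(counts).hyper_flags == flag_hypermutated(shuffled).hyper_flags
        # raising a flagged sample's count never unflags it
        profile = flag_hypermutated({**counts, "S0": 1000})
        assert "S0" in profile.hyper_samples
        profile2 = flag_hypermutated({**counts, "S0": 2000})
        assert "S0" in profile2.hyper_samples


def _doublet(carriers, gene="G"):
    cm = {s: ("missense", 0.4) for s in carriers}
    pm_i = make_pm(gene, 1, cm)
    pm_j = make_pm(gene, 2, cm)
    n = len(carriers)
    return Doublet(
        gene=gene, pm_i=pm_i, pm_j=pm_j, table=ContingencyTable(n, 0, 0, 100 - n),
        p_value=1e-5, q_value=1e-4, odds_ratio=40.0, or_corrected=False,
    )


class TestExcludeHyperDoublets:
    def test_mode_semantics(self):
        d = _doublet(["S1", "S2", "S3"])
        profile = flag_hypermutated({**{f"S{i}": 1 for i in range(1, 9)}, "S1": 500})
        excluded, retained = exclude_hyper_doublets([d], profile, mode="any_carrier")
        assert excluded == [d]
        d2 = _doublet(["S1", "S2", "S3"])
        excluded2, retained2 = exclude_hyper_doublets([d2], profile, mode="all_carriers")
        assert retained2 == [d2]

    def test_partition(self):
        ds = [_doublet(["S1"]), _doublet(["S2"]), _doublet(["S3"])]
        profile = flag_hypermutated({**{f"S{i}": 1 for i in range(1, 9)}, "S2": 500})
        excluded, retained = exclude_hyper_doublets(ds, profile)
        assert sorted(map(id, excluded + retained)) == sorted(map(id, ds))
        assert not set(map(id, excluded)) & set(map(id, retained))

    def test_no_hyper_nothing_excluded(self):
        ds = [_doublet(["S1"])]
        profile = flag_hypermutated({f"S{i}": 3 for i in range(1, 9)})
        excluded, retained = exclude_hyper_doublets(ds, profile)
        assert excluded == [] and retained == ds


class TestRobustnessFisher:
    def test_rebuilt_table_small(self):
        d = _doublet(["S1", "S2"])
        res = robustness_fisher(d, {"S1", "S2", "S3", "S4"}, 4)
        assert (res["a"], res["b"], res["c"], res["d"]) == (2, 0, 0, 2)
        assert res["p"] == pytest.approx(1 / 3)
        assert not res["significant"]

    def test_identity_when_no_samples_flagged(self):
        d = _doublet([f"S{i}" for i in range(5)])
        full = {f"S{i}" for i in range(100)}
        res = robustness_fisher(d, full, 100)
        assert res["p"] == pytest.approx(
            fisher_two_sided_oracle(5, 0, 0, 95), rel=1e-9
        )
        assert res["significant"]

    def test_all_carriers_hyper(self):
        d = _doublet(["S1", "S2"])
        res = robustness_fisher(d, {"S5", "S6", "S7"}, 3)
        assert res["a"] == 0 and not res["significant"] and res["note"]


class TestPermutationBurdenTest:
    def test_strict_exceedance_definition(self):
        """Double=[10] vs Single=[1,1]: no permuted arrangement strictly beats the
        observed statistic, so both the exact and Monte-Carlo p are 0."""
        exact = permutation_p_exact([10], [1, 1])
        assert exact == 0.0
        res = permutation_burden_test([10], [1, 1], B=5000, seed=1)
        assert res.observed_stat == pytest.approx(9.0)
        se = 3 * np.sqrt(max(exact * (1 - exact), 1e-12) / res.B)
        assert abs(res.p_value - exact) <= max(se, 1e-9)

    def test_identical_constant_groups(self):
        res = permutation_burden_test([5, 5], [5, 5, 5], B=1000, seed=3)
        assert res.observed_stat == 0.0
        assert res.N_exceed == 0 and res.p_value == 0.0

    def test_antisymmetry(self):
        r1 = permutation_burden_test([3, 9], [1, 2, 4], B=100, seed=0)
        r2 = permutation_burden_test([1, 2, 4], [3, 9], B=100, seed=0)
        assert r1.observed_stat == pytest.approx(-r2.observed_stat)

    @pytest.mark.parametrize(
        "double,single",
        [
            ([4, 7], [1, 2, 3]),
            ([1, 2], [3, 4, 5, 6]),
            ([9, 1, 5], [5, 5, 2, 7]),
            ([2], [2, 3, 2, 8, 1, 1, 4]),
        ],
    )
    def test_monte_carlo_matches_enumeration(self, double, single):
        """MC p within 3 binomial standard errors of the exhaustive p (total n <= 8)."""
        exact = permutation_p_exact(double, single)
        res = permutation_burden_test(double, single, B=5000, seed=42)
        tol = 3 * np.sqrt(max(exact * (1 - exact), 1e-12) / res.B) + 1e-9
        assert abs(res.p_value - exact) <= tol

    def test_p_times_b_is_integer_count(self):
        res = permutation_burden_test([9, 1], [2, 2, 2], B=500, seed=7)
        assert res.p_value * res.B == res.N_exceed

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            permutation_burden_test([], [1], seed=0)
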