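import numpy as np
import pytest
from scipy.stats import fisher_exact

from latentdoublet.discovery import (
    ContingencyTable,
    build_contingency,
    enumerate_candidates,
    index_positions,
    test_candidates as run_fisher_bh,
)
from latentdoublet.maf_io import Cohort

from conftest import make_cohort, make_pm
from oracles import bh_qvalues_oracle, fisher_two_sided_oracle


class TestIndexPositions:
    def test_same_position_collapses_regardless_of_residue(self):
        cohort = make_cohort(
            [
                {"sample_id": "S1", "gene": "PIK3CA", "protein_position": 545, "alt_aa": "K", "t_alt_count": 40},
                {"sample_id": "S1", "gene": "PIK3CA", "protein_position": 545, "alt_aa": "Q", "t_alt_count": 30},
                {"sample_id": "S2", "gene": "PIK3CA", "protein_position": 545, "alt_aa": "K", "t_alt_count": 20},
            ]
        )
        index = index_positions(cohort)
        (pm,) = index["PIK3CA"]
        assert pm.carriers == {"S1", "S2"}
        # one carrier entry; VAF is the maximum over the sample's records there
        assert pm.vaf_by_carrier["S1"] == pytest.approx(0.40)

    def test_empty_cohort(self):
        cohort = make_cohort([{}])
        assert index_positions(Cohort(cohort.df.iloc[0:0])) == {}


class TestEnumerateCandidates:
    def test_min_carrier_eligibility(self):
        pms = [
            make_pm(position=1, carriers={f"S{i}": ("missense", 0.4) for i in range(4)}),
            make_pm(position=2, carriers={f"S{i}": ("missense", 0.4) for i in range(3)}),
            make_pm(position=3, carriers={f"S{i}": ("missense", 0.4) for i in range(2)}),
        ]
        pairs = enumerate_candidates({"GENE": pms}, min_carriers=3)
        assert len(pairs) == 1
        assert {p.position for p in pairs[0]} == {1, 2}

    @pytest.mark.parametrize("m", [1, 2, 5, 8])
    def test_combinatorial_count(self, m):
        pms = [
            make_pm(position=k, carriers={f"S{i}": ("missense", 0.4) for i in range(3)})
            for k in range(1, m + 1)
        ]
        pairs = enumerate_candidates({"GENE": pms})
        assert len(pairs) == m * (m - 1) // 2


class TestBuildContingency:
    def test_set_arithmetic(self):
        cohort = make_cohort([{"sample_id": f"S{i}"} for i in range(1, 11)])
        pm_i = make_pm(position=1, carriers={s: ("missense", 0.4) for s in ["S1", "S2", "S3"]})
        pm_j = make_pm(position=2, carriers={s: ("missense", 0.4) for s in ["S1", "S2", "S4"]})
        t = build_contingency((pm_i, pm_j), cohort)
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 6)
        assert t.n == cohort.N

    def test_disjoint_carriers(self):
        cohort = make_cohort([{"sample_id": f"S{i}"} for i in range(1, 6)])
        pm_i = make_pm(position=1, carriers={"S1": ("missense", 0.4)})
        pm_j = make_pm(position=2, carriers={"S2": ("missense", 0.4)})
        assert build_contingency((pm_i, pm_j), cohort).a == 0

    def test_corrupt_cohort_detected(self):
        cohort = make_cohort([{"sample_id": "S1"}])
        pm_i = make_pm(position=1, carriers={s: ("missense", 0.4) for s in ["S1", "S2"]})
        pm_j = make_pm(position=2, carriers={"S3": ("missense", 0.4)})
        with pytest.raises(ValueError, match="corrupt"):
            build_contingency((pm_i, pm_j), cohort)


class TestFisherOracle:
    def test_small_table_p_equals_enumeration(self):
        # (2,0,0,2): hypergeometric support {0,1,2}; only a=2 is as unlikely
        p = fisher_exact([[2, 0], [0, 2]], alternative="two-sided")[1]
        assert p == pytest.approx(1 / 3)
        assert fisher_two_sided_oracle(2, 0, 0, 2) == pytest.approx(1 / 3)

    def test_exhaustive_small_n(self):
        """Implementation p equals exact hypergeometric enumeration, all tables N <= 12."""
        for n in range(1, 13):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        p_impl = fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
                        p_oracle = fisher_two_sided_oracle(a, b, c, d)
                        assert p_impl == pytest.approx(p_oracle, rel=1e-9), (a, b, c, d)


class TestBHOracle:
    def test_worked_example(self):
        """p = {0.01,0.02,0.03,0.04}, m=4: q_i = min over tail of p_(j)*4/j = 0.04 each."""
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])
        assert bh_qvalues_oracle([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_random_vectors_match_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        for m in (1, 2, 7, 100):
            p = rng.random(m)
            assert multipletests(p, method="fdr_bh")[1] == pytest.approx(
                bh_qvalues_oracle(list(p)), rel=1e-12
            )


class TestTestCandidates:
    @pytest.fixture
    def two_pair_cohort(self):
        # positions 1 & 2 perfectly co-occur in 6 of 40 samples; positions 3 & 4 disjoint
        rows = []
        for i in range(6):
            rows += [
                {"sample_id": f"C{i}", "gene": "G1", "protein_position": 1},
                {"sample_id": f"C{i}", "gene": "G1", "protein_position": 2},
            ]
        for i in range(4):
            rows.append({"sample_id": f"X{i}", "gene": "G1", "protein_position": 3})
            rows.append({"sample_id": f"Y{i}", "gene": "G1", "protein_position": 4})
        rows += [{"sample_id": f"B{i}", "gene": "G2", "protein_position": 9} for i in range(30)]
        return make_cohort(rows)

    def test_significant_cooccurrence_found(self, two_pair_cohort):
        index = index_positions(two_pair_cohort)
        cands = enumerate_candidates(index)
        doublets = run_fisher_bh(cands, two_pair_cohort)
        found = {(d.pos_i, d.pos_j) for d in doublets}
        assert (1, 2) in found
        d12 = next(d for d in doublets if (d.pos_i, d.pos_j) == (1, 2))
        assert (d12.table.a, d12.table.b, d12.table.c) == (6, 0, 0)
        assert d12.or_corrected  # zero cells -> Haldane correction
        assert d12.odds_ratio > 1
        assert d12.carriers == {f"C{i}" for i in range(6)}

    def test_zero_overlap_never_cooccurring(self, two_pair_cohort):
        index = index_positions(two_pair_cohort)
        cands = enumerate_candidates(index)
        all_tested = run_fisher_bh(cands, two_pair_cohort, return_all=True)
        d34 = next(d for d in all_tested if (d.pos_i, d.pos_j) == (3, 4))
        assert d34.table.a == 0
        assert d34.odds_ratio < 1  # corrected OR below 1 for a=0 with b,c > 0

    def test_invariant_to_record_order(self, two_pair_cohort):
        df = two_pair_cohort.df
        shuffled = Cohort(df.sample(frac=1, random_state=5).reset_index(drop=True))
        a = run_fisher_bh(enumerate_candidates(index_positions(two_pair_cohort)), two_pair_cohort)
        b = run_fisher_bh(enumerate_candidates(index_positions(shuffled)), shuffled)
        assert [(d.gene, d.pos_i, d.pos_j, d.p_value, d.q_value) for d in a] == [
            (d.gene, d.pos_i, d.pos_j, d.p_value, d.q_value) for d in b
        ]

    def test_empty_input(self, two_pair_cohort):
        assert run_fisher_bh([], two_pair_cohort) == []


def test_contingency_cells_nonnegative():
    with pytest.raises(ValueError):
        ContingencyTable(1, -1, 0, 0)
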