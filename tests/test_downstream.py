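"""Phase segmentation, robust rank aggregation, master regulators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coregulon import aggregate_ranks, master_regulators, rho_score, segment_phases
from coregulon.licorn import GRN, LocalModel

from oracles import brute_rho, brute_segment, hypergeom_tail_exact


def infl_frame(x, tfs=None):
    """samples-by-dims array -> TF x sample influence frame."""
    x = np.asarray(x, dtype=float)
    tfs = tfs or [f"tf{i}" for i in range(x.shape[1])]
    samples = [f"s{j:02d}" for j in range(x.shape[0])]
    return pd.DataFrame(x.T, index=tfs, columns=samples)


class TestSegmentPhases:
    def test_constant_matrix_single_phase(self):
        seg = segment_phases(infl_frame(np.ones((10, 3))), max_phases=5)
        assert seg.n_phases == 1
        assert seg.boundaries == []
        assert seg.labels == [1] * 10

    def test_single_planted_shift_found_exactly(self):
        x = np.zeros((26, 4))
        x[13:] = 5.0
        seg = segment_phases(infl_frame(x), n_phases=2)
        assert seg.boundaries == [13]
        # exhaustive single-split oracle
        cost, cuts = brute_segment(x, 2)
        assert cuts == [13]
        assert seg.cost == pytest.approx(cost, abs=1e-9)

    def test_two_planted_shifts_auto_select_three_phases(self, rng):
        x = np.zeros((24, 3))
        x[8:16] += 4.0
        x[16:] -= 4.0
        x += rng.normal(0, 0.2, size=x.shape)
        seg = segment_phases(infl_frame(x), max_phases=8)
        assert seg.n_phases == 3
        assert seg.boundaries == [8, 16]

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_dp_matches_exhaustive_search(self, k, rng):
        x = rng.normal(size=(11, 3))
        seg = segment_phases(infl_frame(x), n_phases=k)
        cost, cuts = brute_segment(x, k)
        assert seg.cost == pytest.approx(cost, abs=1e-9)
        assert seg.boundaries == cuts

    def test_cost_non_increasing_in_segments(self, rng):
        x = rng.normal(size=(12, 4))
        costs = [segment_phases(infl_frame(x), n_phases=k).cost
                 for k in range(1, 7)]
        assert all(a >= b - 1e-9 for a, b in zip(costs, costs[1:]))

    def test_max_phases_exceeding_samples_rejected(self):
        with pytest.raises(ValueError):
            segment_phases(infl_frame(np.ones((4, 2))), max_phases=5)

    def test_rows_with_undefined_entries_dropped(self):
        x = np.zeros((10, 2))
        x[5:, 0] = 3.0
        frame = infl_frame(x)
        frame.loc["tf1", :] = np.nan
        seg = segment_phases(frame, n_phases=2)
        assert seg.boundaries == [5]


class TestAggregateRanks:
    def test_single_list_top_rank(self):
        frame = infl_frame(np.array([[10, 9, 8, 7, 6, 5, 4, 3, 2, 1]]).T.reshape(1, 10).T)
        # one sample, ten TFs, tf0 strongest
        frame = pd.DataFrame({"s0": np.arange(10, 0, -1.0)},
                             index=[f"tf{i}" for i in range(10)])
        res = aggregate_ranks(frame, mode="signed")
        top = res.set_index("tf").loc["tf0"]
        assert top["rho_score"] == pytest.approx(0.1)
        assert top["aggregate_rank"] == 1

    def test_consistent_top_in_three_lists(self):
        vals = np.tile(np.arange(10, 0, -1.0)[:, None], (1, 3))
        frame = pd.DataFrame(vals, index=[f"tf{i}" for i in range(10)],
                             columns=["s0", "s1", "s2"])
        res = aggregate_ranks(frame, mode="signed").set_index("tf")
        # brute-force order-statistic oracle for ranks (0.1, 0.1, 0.1)
        assert brute_rho([0.1, 0.1, 0.1]) == pytest.approx(0.001, abs=1e-12)
        assert res.loc["tf0", "rho_score"] == pytest.approx(0.001, abs=1e-12)
        assert res.loc["tf0", "corrected_score"] == pytest.approx(0.01, abs=1e-12)

    def test_last_everywhere_rho_one(self):
        vals = np.tile(np.arange(10, 0, -1.0)[:, None], (1, 4))
        frame = pd.DataFrame(vals, index=[f"tf{i}" for i in range(10)],
                             columns=[f"s{j}" for j in range(4)])
        res = aggregate_ranks(frame, mode="signed").set_index("tf")
        assert res.loc["tf9", "rho_score"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_rho_matches_binomial_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 8))
        m = int(rng.integers(2, 11))
        ranks = rng.integers(1, m + 1, size=n) / m
        assert rho_score(ranks) == pytest.approx(brute_rho(ranks), abs=1e-12)

    def test_improving_a_rank_never_raises_rho(self, rng):
        for _ in range(20):
            r = np.sort(rng.uniform(size=4))
            j = rng.integers(4)
            better = r.copy()
            better[j] *= 0.5
            assert rho_score(better) <= rho_score(r) + 1e-12

    def test_absolute_mode_ranks_by_magnitude(self):
        frame = pd.DataFrame({"s0": [5.0, -9.0, 1.0]},
                             index=["tfA", "tfB", "tfC"])
        res = aggregate_ranks(frame, mode="absolute")
        assert list(res["tf"]) == ["tfB", "tfA", "tfC"]
        signed = aggregate_ranks(frame, mode="signed")
        assert list(signed["tf"]) == ["tfA", "tfC", "tfB"]

    def test_nan_entries_excluded_per_list(self):
        frame = pd.DataFrame(
            {"s0": [3.0, 2.0, 1.0], "s1": [3.0, np.nan, 1.0]},
            index=["tfA", "tfB", "tfC"],
        )
        res = aggregate_ranks(frame, mode="signed").set_index("tf")
        assert res.loc["tfB", "n_lists"] == 1
        assert res.loc["tfA", "n_lists"] == 2

    def test_empty_subset_rejected(self):
        frame = pd.DataFrame({"s0": [1.0]}, index=["tfA"])
        with pytest.raises(ValueError):
            aggregate_ranks(frame, samples=[])


def regulon_grn(assignments):
    """assignments: tf -> list of target genes (all activated)."""
    models = {}
    for tf, targets in assignments.items():
        for g in targets:
            if g in models:
                acts = tuple(sorted(set(models[g].activators) | {tf}))
                models[g] = LocalModel(g, acts, ())
            else:
                models[g] = LocalModel(g, (tf,), ())
    return GRN(models=models)


class TestMasterRegulators:
    def test_zero_overlap_p_one(self):
        grn = regulon_grn({"tfA": ["g1", "g2"], "tfB": ["g3", "g4"]})
        res = master_regulators(grn, {"g3", "g4"})
        pA = next(r for r in res if r.tf == "tfA")
        assert pA.p_value == pytest.approx(1.0)

    def test_gene_set_equal_universe_p_one(self):
        grn = regulon_grn({"tfA": ["g1", "g2"], "tfB": ["g2", "g3"]})
        res = master_regulators(grn, {"g1", "g2", "g3"})
        assert all(r.p_value == pytest.approx(1.0) for r in res)

    def test_factorial_oracle_example(self):
        # universe 20, gene set 5, regulon 8, overlap 4 -> 7280/125970
        genes = [f"g{k:02d}" for k in range(20)]
        gene_set = set(genes[:5])
        regulon = genes[1:5] + genes[10:14]  # overlap 4
        grn = regulon_grn({"tfA": regulon, "tfB": genes})
        res = master_regulators(grn, gene_set, universe=set(genes))
        pA = next(r for r in res if r.tf == "tfA")
        assert pA.overlap == 4
        assert pA.p_value == pytest.approx(7280 / 125970, abs=1e-12)
        assert pA.p_value == pytest.approx(0.0578, abs=5e-5)

    def test_empty_gene_set_rejected(self):
        grn = regulon_grn({"tfA": ["g1"]})
        with pytest.raises(ValueError):
            master_regulators(grn, set())

    def test_null_pvalues_approximately_uniform(self):
        # 200 TFs with random regulons, random gene set: hypergeometric
        # p-values should not deviate from uniform (KS at the 1% level)
        rng = np.random.default_rng(2024)
        genes = [f"g{k:03d}" for k in range(400)]
        assignments = {
            f"tf{t:03d}": list(rng.choice(genes, size=30, replace=False))
            for t in range(200)
        }
        grn = regulon_grn(assignments)
        gene_set = set(rng.choice(genes, size=60, replace=False))
        res = master_regulators(grn, gene_set, universe=set(genes))
        # mid-p style smoothing for the discrete null: draw u in (p_lo, p]
        pvals = []
        for r in res:
            lo = hypergeom_tail_exact(r.overlap + 1, r.universe_count,
                                      r.geneset_count, r.target_count)
            pvals.append(rng.uniform(lo, r.p_value))
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_planted_enriched_regulon_ranked_first(self):
        rng = np.random.default_rng(5)
        genes = [f"g{k:03d}" for k in range(300)]
        gene_set = set(genes[:40])
        assignments = {
            f"tf{t:02d}": list(rng.choice(genes, size=25, replace=False))
            for t in range(30)
        }
        # planted TF: half its regulon inside the gene set (odds ratio >> 4)
        assignments["tfXX"] = genes[:13] + genes[100:112]
        grn = regulon_grn(assignments)
        res = master_regulators(grn, gene_set, universe=set(genes))
        assert res[0].tf == "tfXX"

    def test_side_restriction(self):
        models = {
            "g1": LocalModel("g1", ("tfA",), ()),
            "g2": LocalModel("g2", (), ("tfA",)),
        }
        grn = GRN(models=models)
        res_act = master_regulators(grn, {"g1"}, side="activated")
        res_rep = master_regulators(grn, {"g1"}, side="repressed")
        a = next(r for r in res_act if r.tf == "tfA")
        r_ = next(r for r in res_rep if r.tf == "tfA")
        assert a.overlap == 1 and r_.overlap == 0

    def test_bh_column_present_and_sorted(self):
        grn = regulon_grn({"tfA": ["g1", "g2"], "tfB": ["g3"]})
        res = master_regulators(grn, {"g1"})
        assert all(r.p_bh is not None for r in res)
        assert [r.p_value for r in res] == sorted(r.p_value for r in res)
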