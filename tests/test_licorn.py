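"""Co-regulator mining, candidate selection and sign-constrained fitting."""

import numpy as np
import pytest

from coregulon import (
    PipelineConfig,
    RegulatorList,
    discretize,
    fit_local_model,
    infer_grn,
    mine_coreg_sets,
    score_candidate_discrete,
    select_candidates,
)
from coregulon.licorn import CoregSet, LocalModel, collective_state

from conftest import make_disc, make_expr
from oracles import brute_discrete_score, brute_mine


def random_states(rng, n_tfs, n_samples, p_zero=0.4):
    vals = rng.choice([-1, 0, 1], size=(n_tfs, n_samples),
                      p=[(1 - p_zero) / 2, p_zero, (1 - p_zero) / 2])
    return make_disc(vals, genes=[f"t{i:02d}" for i in range(n_tfs)])


class TestMining:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        disc = random_states(rng, rng.integers(3, 8), rng.integers(5, 15))
        states = {t: disc.row(t) for t in disc.gene_ids}
        for min_sup in (0.0, 0.2, 0.4):
            got = mine_coreg_sets(disc, min_sup, 4)
            expected = brute_mine(states, min_sup, 4)
            assert [(s.members, s.support) for s in got] == expected

    def test_zero_support_threshold_returns_all_subsets(self, rng):
        disc = random_states(rng, 4, 6)
        got = mine_coreg_sets(disc, 0.0, 4)
        assert len(got) == 15  # all nonempty subsets of 4 TFs

    def test_all_zero_tf_absent_from_every_set(self):
        disc = make_disc([[1, 1, 0, 0], [0, 0, 0, 0], [1, 1, -1, 0]],
                         genes=["a", "zero", "c"])
        got = mine_coreg_sets(disc, 0.2, 3)
        assert all("zero" not in s.members for s in got)

    def test_empty_matrix_empty_list(self):
        disc = make_disc(np.empty((0, 4), dtype=int), genes=[])
        assert mine_coreg_sets(disc, 0.1, 3) == []

    def test_downward_closure_of_support(self, rng):
        disc = random_states(rng, 6, 12)
        got = {s.members: s.support for s in mine_coreg_sets(disc, 0.0, 4)}
        for mem, sup in got.items():
            for drop in range(len(mem)):
                sub = mem[:drop] + mem[drop + 1:]
                if sub:
                    assert got[sub] >= sup

    def test_deterministic_order(self, rng):
        disc = random_states(rng, 5, 10)
        a = mine_coreg_sets(disc, 0.1, 3)
        b = mine_coreg_sets(disc, 0.1, 3)
        assert a == b
        sizes = [len(s.members) for s in a]
        assert sizes == sorted(sizes)


class TestDiscreteScore:
    def test_empty_programs_score_mean_abs_over_two(self):
        disc = make_disc([[1, -1, 0, 1]], genes=["g"])
        g = disc.row("g")
        score = score_candidate_discrete(g, (), (), disc)
        assert score == pytest.approx(np.abs(g).mean() / 2)

    def test_perfect_single_activator_scores_zero(self):
        disc = make_disc([[1, -1, 0], [1, -1, 0]], genes=["g", "t"])
        assert score_candidate_discrete(disc.row("g"), ("t",), (), disc) == 0.0

    def test_conflicting_sides_predict_zero(self):
        # a = +1 and i = +1 in the same sample -> prediction 0, error 1 for
        # a gene in state +1
        disc = make_disc([[1], [1], [1]], genes=["g", "a", "i"])
        score = score_candidate_discrete(disc.row("g"), ("a",), ("i",), disc)
        assert score == pytest.approx(0.5)  # |1 - 0| / 2

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_truth_table_oracle(self, seed):
        rng = np.random.default_rng(seed)
        disc = random_states(rng, 5, 12)
        ids = disc.gene_ids
        g = disc.row(ids[0])
        A, I = (ids[1], ids[2]), (ids[3],)
        a = collective_state(A, disc)
        i = collective_state(I, disc)
        assert score_candidate_discrete(g, A, I, disc) == pytest.approx(
            brute_discrete_score(g, a, i)
        )

    def test_permutation_invariance_and_sign_symmetry(self, rng):
        disc = random_states(rng, 4, 10)
        ids = disc.gene_ids
        g = disc.row(ids[0])
        s1 = score_candidate_discrete(g, (ids[1],), (ids[2],), disc)
        perm = rng.permutation(10)
        disc_p = make_disc(disc.states.to_numpy()[:, perm], genes=ids)
        s2 = score_candidate_discrete(disc_p.row(ids[0]), (ids[1],), (ids[2],), disc_p)
        assert s1 == pytest.approx(s2)
        # swapping A and I on a sign-flipped gene leaves the score unchanged
        disc_n = make_disc(-disc.states.to_numpy(), genes=ids)
        s3 = score_candidate_discrete(-g, (ids[2],), (ids[1],), disc)
        s4 = score_candidate_discrete(g, (ids[1],), (ids[2],), disc)
        assert s3 == pytest.approx(s4)

    def test_overlapping_sides_rejected(self, rng):
        disc = random_states(rng, 3, 5)
        ids = disc.gene_ids
        with pytest.raises(ValueError):
            score_candidate_discrete(disc.row(ids[0]), (ids[1],), (ids[1],), disc)


def brute_candidates(gene, sets, disc, thresh):
    """All disjoint (A, I) pairs from sets plus empty sides, scored."""
    pool = [()] + [s.members for s in sets if gene not in s.members]
    out = []
    for A in pool:
        for I in pool:
            if A == I == ():
                continue
            if set(A) & set(I):
                continue
            sc = score_candidate_discrete(disc.row(gene), A, I, disc)
            if sc <= thresh:
                out.append((sc, len(A) + len(I), A, I))
    out.sort()
    return [(a, i, s) for s, _, a, i in out]


class TestSelectCandidates:
    def _fixture(self, rng):
        disc = random_states(rng, 4, 10, p_zero=0.3)
        gene_states = disc.states.iloc[0].to_numpy()
        disc.states.loc["gene"] = gene_states  # gene mirrors t00
        sets = mine_coreg_sets(
            make_disc(disc.states.loc[[f"t{i:02d}" for i in range(4)]].to_numpy(),
                      genes=[f"t{i:02d}" for i in range(4)]), 0.0, 3)
        return disc, sets

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_pair_search(self, seed):
        rng = np.random.default_rng(seed)
        disc, sets = self._fixture(rng)
        got = select_candidates("gene", sets, disc, search_thresh=0.5,
                                max_candidates=10_000, min_gene_support=0.0)
        expected = brute_candidates("gene", sets, disc, 0.5)
        assert [(m.activators, m.inhibitors, pytest.approx(m.discrete_score))
                for m in got] == expected

    def test_perfect_single_activator_ranked_first(self, rng):
        disc, sets = self._fixture(rng)
        got = select_candidates("gene", sets, disc, min_gene_support=0.0)
        assert got[0].activators == ("t00",)
        assert got[0].inhibitors == ()
        assert got[0].discrete_score == 0.0

    def test_zero_threshold_keeps_only_exact_agreement(self, rng):
        disc, sets = self._fixture(rng)
        got = select_candidates("gene", sets, disc, search_thresh=0.0,
                                min_gene_support=0.0)
        assert got and all(m.discrete_score == 0.0 for m in got)

    def test_low_support_gene_skipped(self):
        disc = make_disc([[0] * 10, [1] * 10], genes=["gene", "t"])
        sets = [CoregSet(("t",), 1.0)]
        assert select_candidates("gene", sets, disc, min_gene_support=0.1) == []


class TestFitLocalModel:
    def test_exact_linear_fit_scores_one(self, rng):
        t1 = rng.normal(size=8)
        t2 = rng.normal(size=8)
        gene = (t1 + t2) / 2
        expr = make_expr(np.vstack([gene, t1, t2]), genes=["g", "t1", "t2"])
        assert fit_local_model(expr, "g", ("t1", "t2"), ()) == pytest.approx(1.0)

    def test_anticorrelated_activator_clipped_to_zero_fit(self, rng):
        t1 = rng.normal(size=10)
        expr = make_expr(np.vstack([-t1, t1]), genes=["g", "t1"])
        score = fit_local_model(expr, "g", ("t1",), ())
        assert score <= 0.0
        # identical data with the TF as inhibitor fits perfectly
        assert fit_local_model(expr, "g", (), ("t1",)) == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        # planted signs: unconstrained least squares already satisfies the
        # constraints, so the constrained fit must agree exactly
        n = 20
        mA = rng.normal(size=n)
        mI = rng.normal(size=n)
        y = 0.3 + 1.2 * mA - 0.8 * mI + rng.normal(0, 0.05, size=n)
        expr = make_expr(np.vstack([y, mA, mI]), genes=["g", "a", "i"])
        X = np.column_stack([np.ones(n), mA, mI])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert beta[1] > 0 and beta[2] < 0
        resid = y - X @ beta
        r2 = 1 - (resid ** 2).sum() / ((y - y.mean()) ** 2).sum()
        adj = 1 - (1 - r2) * (n - 1) / (n - 3)
        assert fit_local_model(expr, "g", ("a",), ("i",)) == pytest.approx(adj, abs=1e-10)

    def test_zero_variance_gene_warns_zero(self, rng):
        expr = make_expr(np.vstack([np.full(6, 2.0), rng.normal(size=6)]),
                         genes=["g", "t"])
        with pytest.warns(UserWarning, match="zero-variance"):
            assert fit_local_model(expr, "g", ("t",), ()) == 0.0

    def test_score_never_exceeds_one(self, rng):
        for _ in range(10):
            vals = rng.normal(size=(3, 9))
            expr = make_expr(vals, genes=["g", "a", "i"])
            assert fit_local_model(expr, "g", ("a",), ("i",)) <= 1.0

    def test_requires_four_samples(self, rng):
        expr = make_expr(rng.normal(size=(2, 3)), genes=["g", "t"])
        with pytest.raises(ValueError):
            fit_local_model(expr, "g", ("t",), ())


class TestInferGrn:
    def _instance(self, rng, n_tfs=6, n_genes=8, n_samples=14):
        tfs = [f"t{i:02d}" for i in range(n_tfs)]
        genes = [f"g{i:02d}" for i in range(n_genes)]
        vals = rng.normal(size=(n_tfs + n_genes, n_samples))
        # plant a couple of genes driven by TF means so models exist
        for j in range(n_genes):
            a, b = rng.choice(n_tfs, size=2, replace=False)
            vals[n_tfs + j] = 0.8 * vals[a] - 0.6 * vals[b] \
                + rng.normal(0, 0.1, size=n_samples)
        expr = make_expr(vals, genes=tfs + genes)
        disc = discretize(expr)
        return expr, disc, RegulatorList(frozenset(tfs))

    def test_deterministic_across_runs(self, rng):
        expr, disc, tfs = self._instance(rng)
        cfg = PipelineConfig(min_coreg_support=0.1)
        g1 = infer_grn(expr, disc, tfs, config=cfg)
        g2 = infer_grn(expr, disc, tfs, config=cfg)
        assert g1.models == g2.models

    def test_matches_stepwise_reference_path(self, rng):
        """The vectorized inference equals select -> fit -> merge per gene."""
        from coregulon import merge_and_select
        expr, disc, tfs = self._instance(rng)
        cfg = PipelineConfig(min_coreg_support=0.1, use_evidence=False)
        grn = infer_grn(expr, disc, tfs, config=cfg)
        mined = mine_coreg_sets(
            make_disc(disc.states.loc[sorted(tfs.tf_ids)].to_numpy(),
                      genes=sorted(tfs.tf_ids)),
            cfg.min_coreg_support, cfg.max_coreg)
        for gene in sorted(grn.models):
            cands = select_candidates(gene, mined, disc,
                                      search_thresh=cfg.search_thresh,
                                      max_candidates=cfg.max_candidates,
                                      min_gene_support=cfg.min_gene_support)
            for m in cands:
                m.fit_score = fit_local_model(expr, gene, m.activators, m.inhibitors)
            sel = merge_and_select(cands, use_evidence=False)
            chosen = sel.candidates[sel.chosen_index]
            got = grn.models[gene]
            assert (got.activators, got.inhibitors) == (chosen.activators,
                                                        chosen.inhibitors)
            assert got.merged_score == pytest.approx(chosen.merged_score, abs=1e-8)

    def test_no_eligible_gene_gives_empty_grn(self):
        disc = make_disc(np.zeros((3, 8), dtype=int), genes=["t0", "t1", "g0"])
        expr = make_expr(np.ones((3, 8)), genes=["t0", "t1", "g0"])
        with pytest.warns(UserWarning):
            grn = infer_grn(expr, disc, RegulatorList(frozenset({"t0", "t1"})))
        assert grn.models == {}

    def test_tf_never_regulates_itself(self, rng):
        expr, disc, tfs = self._instance(rng)
        cfg = PipelineConfig(min_coreg_support=0.1, include_tf_targets=True)
        grn = infer_grn(expr, disc, tfs, config=cfg)
        for gene, m in grn.models.items():
            assert gene not in m.activators + m.inhibitors

    def test_regulon_index_inverts_models(self, rng):
        expr, disc, tfs = self._instance(rng)
        grn = infer_grn(expr, disc, tfs, config=PipelineConfig(min_coreg_support=0.1))
        n_edges = 0
        for tf, (Ar, Ir) in grn.regulons.items():
            for g in Ar:
                assert tf in grn.models[g].activators
            for g in Ir:
                assert tf in grn.models[g].inhibitors
            n_edges += len(Ar) + len(Ir)
        assert n_edges == grn.n_interactions


class TestLocalModelInvariants:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            LocalModel("g", ("t1",), ("t1",))

    def test_self_regulation_rejected(self):
        with pytest.raises(ValueError):
            LocalModel("g", ("g",), ())
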