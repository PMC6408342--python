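import numpy as np
import pytest

from corrnull import (
    FoodWeb,
    IncidenceMatrix,
    SwapBudget,
    build_ensemble,
    classify_links,
    constant_correlation,
    default_swap_budget,
    group_correlation,
    random_binary_matrix,
    randomize_bipartite,
    randomize_foodweb,
)
from corrnull.nullmodels import BipartiteSwapChain


class TestSwapBudget:
    def test_default_heuristic(self):
        A = random_binary_matrix(5, 5, 0.5, seed=0)
        L = A.n_links
        b = default_swap_budget(A)
        assert b.target_accepted == 2 * L
        assert b.max_trials == 100 * L

    @pytest.mark.parametrize("links,target", [(5, 10), (100, 200)])
    def test_target_is_twice_link_count(self, links, target):
        values = np.zeros((links, 2), dtype=int)
        values[:, 0] = 1
        A = IncidenceMatrix(values, [f"r{i}" for i in range(links)], ["c1", "c2"])
        assert default_swap_budget(A).target_accepted == target

    def test_invalid_budget_rejected(self):
        with pytest.raises(ValueError):
            SwapBudget(target_accepted=0, max_trials=10)
        with pytest.raises(ValueError):
            SwapBudget(target_accepted=10, max_trials=5)


class TestBipartite:
    def test_identity_swaps_to_anti_identity(self, identity2):
        out = randomize_bipartite(
            identity2, None, SwapBudget(1, 1000), seed=0
        )
        assert np.array_equal(out.values, [[0, 1], [1, 0]])

    def test_all_ones_has_no_valid_swap(self):
        A = IncidenceMatrix(np.ones((2, 2), dtype=int), ["r1", "r2"], ["c1", "c2"])
        with pytest.warns(UserWarning, match="trial cap"):
            out = randomize_bipartite(A, None, SwapBudget(1, 50), seed=0)
        assert np.array_equal(out.values, A.values)

    @pytest.mark.parametrize("seed", range(10))
    def test_marginals_preserved(self, seed):
        A = random_binary_matrix(8, 10, 0.35, seed=seed)
        out = randomize_bipartite(A, None, seed=seed)
        assert np.array_equal(out.values.sum(axis=1), A.values.sum(axis=1))
        assert np.array_equal(out.values.sum(axis=0), A.values.sum(axis=0))

    def test_informed_acceptance_waiting_time(self):
        """With acceptance probability 0.25 for the unique valid proposal the
        mean number of valid trials per accepted swap is about 4."""
        A = IncidenceMatrix(np.eye(2, dtype=int), ["r1", "r2"], ["c1", "c2"])
        P = np.full((2, 2), 0.5)  # product 0.25 for the only swap
        rng = np.random.default_rng(0)
        waits = []
        for _ in range(400):
            chain = BipartiteSwapChain(A.values, P, rng)
            trials = 0
            while True:
                trials += 1
                if chain.step():
                    break
            waits.append(trials)
        assert np.mean(waits) == pytest.approx(4.0, rel=0.15)


class TestFoodWeb:
    @pytest.mark.parametrize("seed", range(25))
    def test_link_classes_and_degrees_preserved(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        A = (rng.random((n, n)) < 0.15).astype(int)
        W = FoodWeb(A, [f"s{i}" for i in range(n)])
        out = randomize_foodweb(W, None, seed=seed + 1000)
        before, after = classify_links(W), classify_links(out)
        assert (after.n_single, after.n_double, after.n_cannibal) == (
            before.n_single,
            before.n_double,
            before.n_cannibal,
        )
        assert after.in_degree == before.in_degree
        assert after.out_degree == before.out_degree

    def test_cannibal_links_never_move(self):
        rng = np.random.default_rng(3)
        A = (rng.random((10, 10)) < 0.2).astype(int)
        np.fill_diagonal(A, [1, 0, 1, 0, 0, 1, 0, 0, 0, 0])
        W = FoodWeb(A, [f"s{i}" for i in range(10)])
        out = randomize_foodweb(W, None, seed=4)
        assert np.array_equal(np.diag(out.values), np.diag(W.values))

    def test_lone_double_cannot_swap(self):
        A = np.zeros((4, 4), dtype=int)
        A[0, 1] = A[1, 0] = 1  # one double link, no singles
        W = FoodWeb(A, list("abcd"))
        with pytest.warns(UserWarning, match="trial cap"):
            out = randomize_foodweb(W, None, SwapBudget(1, 40), seed=0)
        assert np.array_equal(out.values, W.values)

    def test_single_swaps_never_create_doubles(self):
        """Reciprocal-creating proposals are rejected, so the double count is
        conserved even in dense webs where they would otherwise be common."""
        rng = np.random.default_rng(11)
        A = (rng.random((12, 12)) < 0.3).astype(int)
        W = FoodWeb(A, [f"s{i}" for i in range(12)])
        before = classify_links(W)
        for seed in range(5):
            out = randomize_foodweb(W, None, seed=seed)
            assert classify_links(out).n_double == before.n_double


class TestEnsemble:
    def test_size_below_two_rejected(self):
        A = random_binary_matrix(4, 4, 0.5, seed=0)
        with pytest.raises(ValueError, match="size"):
            build_ensemble(A, size=1, seed=0)

    def test_determinism_same_master_seed(self):
        A = random_binary_matrix(6, 8, 0.4, seed=2)
        groups = {c: f"g{i % 2}" for i, c in enumerate(A.col_labels)}
        V = group_correlation(groups, 0.01)
        for model in ("uninformed", "informed", "misinformed"):
            e1 = build_ensemble(A, model, V=V, size=4, seed=42)
            e2 = build_ensemble(A, model, V=V, size=4, seed=42)
            assert e1.seeds == e2.seeds
            for M1, M2 in zip(e1.matrices, e2.matrices):
                assert np.array_equal(M1.values, M2.values)

    def test_different_seeds_differ(self):
        A = random_binary_matrix(6, 8, 0.4, seed=2)
        e1 = build_ensemble(A, "uninformed", size=4, seed=1)
        e2 = build_ensemble(A, "uninformed", size=4, seed=2)
        assert any(
            not np.array_equal(M1.values, M2.values)
            for M1, M2 in zip(e1.matrices, e2.matrices)
        )

    def test_informed_requires_correlation(self):
        A = random_binary_matrix(4, 4, 0.5, seed=0)
        with pytest.raises(ValueError, match="correlation"):
            build_ensemble(A, "informed", size=2, seed=0)

    def test_provenance_records_model(self):
        A = random_binary_matrix(5, 6, 0.4, seed=1)
        V = constant_correlation(A.col_labels)
        ens = build_ensemble(A, "misinformed", V=V, size=2, seed=0)
        assert ens.probability_provenance["model"] == "misinformed"
        assert ens.probability_provenance["permuted_per_replicate"]

    def test_foodweb_ensemble_replicates_are_foodwebs(self):
        rng = np.random.default_rng(6)
        A = (rng.random((8, 8)) < 0.25).astype(int)
        W = FoodWeb(A, [f"s{i}" for i in range(8)])
        ens = build_ensemble(W, "uninformed", size=3, seed=0)
        assert all(isinstance(M, FoodWeb) for M in ens.matrices)
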