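import subprocess

import numpy as np
import pytest

from corrnull import (
    NAMED_MOTIFS,
    FoodWeb,
    IncidenceMatrix,
    build_ensemble,
    motif_census,
    motif_zscore_profile,
    nodf,
    overlap_fraction,
    random_binary_matrix,
    write_incidence,
    zscore,
)
from oracles import motif_census_oracle


class TestMotifCensus:
    def test_food_chain(self):
        W = FoodWeb(np.array([[0, 1, 0], [0, 0, 1], [0, 0, 0]]), list("abc"))
        counts = motif_census(W).counts
        assert counts[NAMED_MOTIFS["food_chain"]] == 1
        assert sum(counts.values()) == 1

    def test_exploitative_competition(self):
        W = FoodWeb(np.array([[0, 1, 1], [0, 0, 0], [0, 0, 0]]), list("abc"))
        assert motif_census(W).named()["exploitative_competition"] == 1

    def test_apparent_competition(self):
        W = FoodWeb(np.array([[0, 0, 1], [0, 0, 1], [0, 0, 0]]), list("abc"))
        assert motif_census(W).named()["apparent_competition"] == 1

    def test_omnivory(self, chain_web):
        assert motif_census(chain_web).named()["omnivory"] == 1

    def test_three_species_loop(self):
        W = FoodWeb(np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]]), list("abc"))
        assert motif_census(W).named()["three_species_loop"] == 1

    def test_self_loops_excluded(self, chain_web):
        with_cannibal = chain_web.values.copy()
        with_cannibal[0, 0] = 1
        W = FoodWeb(with_cannibal, list(chain_web.labels))
        assert motif_census(W).counts == motif_census(chain_web).counts

    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            motif_census(FoodWeb(np.eye(2, dtype=int), ["a", "b"]))

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        A = (rng.random((n, n)) < rng.uniform(0.1, 0.5)).astype(int)
        W = FoodWeb(A, [f"s{i}" for i in range(n)])
        assert motif_census(W).counts == motif_census_oracle(A)

    def test_invariant_under_relabelling(self):
        rng = np.random.default_rng(99)
        A = (rng.random((9, 9)) < 0.3).astype(int)
        pi = rng.permutation(9)
        W1 = FoodWeb(A, [f"s{i}" for i in range(9)])
        W2 = FoodWeb(A[np.ix_(pi, pi)], [f"s{i}" for i in range(9)])
        assert motif_census(W1).counts == motif_census(W2).counts


class TestNodf:
    def test_perfectly_nested_scores_100(self, nested3):
        assert nodf(nested3) == pytest.approx(100.0)

    def test_checkerboard_scores_0(self, identity2):
        assert nodf(identity2) == pytest.approx(0.0)

    def test_range_and_permutation_invariance(self):
        rng = np.random.default_rng(5)
        for seed in range(5):
            A = random_binary_matrix(7, 9, 0.4, seed=seed)
            v = nodf(A)
            assert 0.0 <= v <= 100.0
            pr, pc = rng.permutation(7), rng.permutation(9)
            B = IncidenceMatrix(
                A.values[np.ix_(pr, pc)],
                [A.row_labels[i] for i in pr],
                [A.col_labels[j] for j in pc],
            )
            assert nodf(B) == pytest.approx(v)

    def test_empty_rows_contribute_zero(self):
        A = IncidenceMatrix([[1, 1], [0, 0]], ["r1", "r2"], ["c1", "c2"])
        # the single row pair involves an empty row; only the column pair
        # (equal marginals) remains: both contribute 0
        assert nodf(A) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_vegan_reference(self, seed, tmp_path):
        """Cross-check against the R vegan implementation of the published
        calculator (decreasing-fill ordering)."""
        A = random_binary_matrix(8, 10, 0.4, seed=seed)
        path = tmp_path / "m.csv"
        write_incidence(A, path)
        script = (
            f'suppressMessages(library(vegan));'
            f'm <- as.matrix(read.csv("{path}", row.names=1));'
            f'cat(sprintf("%.10f", unname(nestednodf(m, order=TRUE, weighted=FALSE)$statistic["NODF"])))'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        assert nodf(A) == pytest.approx(float(out.stdout), abs=1e-8)


class TestZscore:
    def test_centre_of_ensemble(self):
        res = zscore(2.0, [1.0, 2.0, 3.0])
        assert res.z == pytest.approx(0.0)
        assert not res.significant

    def test_two_sd_above_mean_is_significant(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(10.0, 2.0, size=500)
        k = vals.mean() + 2.0 * vals.std(ddof=1)
        res = zscore(k, vals)
        assert res.z == pytest.approx(2.0)
        assert res.significant

    def test_degenerate_ensemble_flagged(self):
        with pytest.warns(UserWarning, match="zero spread"):
            res = zscore(5.0, [5.0, 5.0, 5.0])
        assert np.isnan(res.z)
        assert not res.significant

    def test_location_scale_equivariance(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=100)
        k = 0.7
        z0 = zscore(k, vals).z
        for a, b in [(3.0, -2.0), (0.1, 5.0)]:
            assert zscore(a * k + b, a * vals + b).z == pytest.approx(z0)

    def test_sign_matches_direction(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        assert zscore(10.0, vals).z > 0
        assert zscore(-10.0, vals).z < 0


class TestProfilesAndOverlap:
    def test_profile_zscores_sign_and_degenerate(self):
        rng = np.random.default_rng(8)
        A = (rng.random((10, 10)) < 0.25).astype(int)
        W = FoodWeb(A, [f"s{i}" for i in range(10)])
        ens = build_ensemble(W, "uninformed", size=30, seed=0)
        profile = motif_zscore_profile(W, ens)
        assert set(profile) == set(motif_census(W).counts)
        obs = motif_census(W).counts
        for cls, res in profile.items():
            if not np.isnan(res.z) and res.z != 0:
                assert np.sign(res.z) == np.sign(obs[cls] - res.ensemble_mean)

    def test_overlap_identical_is_one(self, nested3):
        assert overlap_fraction(nested3, nested3) == 1.0

    def test_overlap_disjoint_is_zero(self, identity2):
        anti = IncidenceMatrix([[0, 1], [1, 0]], ["r1", "r2"], ["c1", "c2"])
        assert overlap_fraction(identity2, anti) == 0.0

    def test_overlap_shape_mismatch_rejected(self, identity2, nested3):
        with pytest.raises(ValueError, match="shape"):
            overlap_fraction(identity2, nested3)

    def test_ensemble_overlap_summary(self):
        A = random_binary_matrix(8, 8, 0.4, seed=3)
        ens = build_ensemble(A, "uninformed", size=10, seed=0)
        overlaps = [overlap_fraction(A, M) for M in ens.matrices]
        assert all(0.0 <= f <= 1.0 for f in overlaps)
        assert np.mean(overlaps) < 1.0  # the chain actually moved
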