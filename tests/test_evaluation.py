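import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import mcmda.evaluation as ev
from mcmda.evaluation import (
    global_loocv,
    holdout_scores,
    kfold_cv,
    local_loocv,
    rank_candidates,
    roc_auc,
)
from mcmda.svt import DegenerateInputError, SVTParams, svt_complete
from mcmda.synthetic import simulate

from .conftest import matrix_from_pairs
from .oracles import loocv_enumeration, mann_whitney_auc


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.9], [0.1, 0.2])
        assert auc == 1.0

    def test_all_tied_is_half(self):
        _, auc = roc_auc([0.5], [0.5, 0.5])
        assert auc == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_mann_whitney_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # coarse grid forces ties
        tests = rng.integers(0, 10, size=30) / 10.0
        cands = rng.integers(0, 10, size=200) / 10.0
        _, auc = roc_auc(tests, cands)
        assert auc == pytest.approx(mann_whitney_auc(tests, cands), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        tests = rng.normal(size=25)
        cands = rng.normal(size=100)
        _, auc = roc_auc(tests, cands)
        sk = roc_auc_score(
            np.r_[np.ones(25), np.zeros(100)], np.r_[tests, cands]
        )
        assert auc == pytest.approx(sk, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        tests = rng.normal(size=20)
        cands = rng.normal(size=80)
        _, auc = roc_auc(tests, cands)
        _, auc2 = roc_auc(np.exp(tests), np.exp(cands))
        assert auc == pytest.approx(auc2, abs=1e-12)

    def test_roc_curve_shape(self):
        rng = np.random.default_rng(4)
        roc, _ = roc_auc(rng.normal(size=10), rng.normal(size=40))
        assert tuple(roc[0]) == (0.0, 0.0)
        assert tuple(roc[-1]) == (1.0, 1.0)
        assert np.all(np.diff(roc[:, 0]) >= 0)
        assert np.all(np.diff(roc[:, 1]) >= 0)

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([], [0.1])
        with pytest.raises(ValueError):
            roc_auc([0.1], [])


class TestHoldoutScores:
    def test_empty_holdout_equals_plain_completion(self, tiny_matrix, fast_params):
        X = holdout_scores(tiny_matrix, [], fast_params)
        np.testing.assert_array_equal(X, svt_complete(tiny_matrix, fast_params).X)

    def test_holding_out_everything_is_degenerate(self, tiny_matrix, fast_params):
        with pytest.raises(DegenerateInputError):
            holdout_scores(tiny_matrix, tiny_matrix.omega, fast_params)

    def test_holdout_bookkeeping(self, fast_params):
        A = matrix_from_pairs([(0, 0), (1, 2), (3, 1), (2, 3)], 4, 4)
        training = A.without([(1, 2)])
        assert training.M[1, 2] == 0.0
        assert len(training.omega) == len(A.omega) - 1
        assert (1, 2) not in training.omega
        # original untouched
        assert A.M[1, 2] == 1.0 and (1, 2) in A.omega

    def test_not_a_subset_rejected(self, tiny_matrix, fast_params):
        outside = next(
            (i, j)
            for i in range(tiny_matrix.nm)
            for j in range(tiny_matrix.nd)
            if (i, j) not in tiny_matrix.omega
        )
        with pytest.raises(ValueError):
            holdout_scores(tiny_matrix, [outside], fast_params)


class TestLoocv:
    def test_perfect_scorer_gives_auc_one(self, monkeypatch):
        A = matrix_from_pairs([(0, 0), (1, 1), (2, 2)], 3, 3)
        # scorer that always puts the held-out (and only the known) entries on top
        monkeypatch.setattr(
            ev, "holdout_scores", lambda A_, held, params: A_.M + 0.0
        )
        assert global_loocv(A).auc == 1.0
        assert local_loocv(A).auc == 1.0

    def test_constant_scorer_gives_auc_half(self, monkeypatch):
        A = matrix_from_pairs([(0, 0), (1, 1), (2, 2)], 3, 3)
        monkeypatch.setattr(
            ev, "holdout_scores", lambda A_, held, params: np.ones(A_.M.shape)
        )
        assert global_loocv(A).auc == pytest.approx(0.5)
        assert local_loocv(A).auc == pytest.approx(0.5)

    def test_global_matches_enumeration_oracle(self, fast_params):
        A = simulate(12, 10, 2, 0.2, 0.7, seed=5).observed
        got = global_loocv(A, fast_params)
        oracle_auc, oracle_ranks = loocv_enumeration(A, fast_params, local=False)
        assert got.auc == pytest.approx(oracle_auc, abs=1e-12)
        assert {r.pair: r.rank for r in got.ranks} == pytest.approx(oracle_ranks)

    def test_local_matches_enumeration_oracle(self, fast_params):
        A = simulate(12, 10, 2, 0.2, 0.7, seed=5).observed
        got = local_loocv(A, fast_params)
        oracle_auc, oracle_ranks = loocv_enumeration(A, fast_params, local=True)
        assert got.auc == pytest.approx(oracle_auc, abs=1e-12)
        assert {r.pair: r.rank for r in got.ranks} == pytest.approx(oracle_ranks)

    def test_local_skips_saturated_disease_column(self, fast_params):
        # disease column 0 fully known: its test samples have no candidates
        A = matrix_from_pairs([(0, 0), (1, 0), (0, 1)], 2, 2)
        result = local_loocv(A, fast_params)
        assert set(result.skipped) == {(0, 0), (1, 0)}
        assert [r.pair for r in result.ranks] == [(0, 1)]

    def test_needs_two_known_associations(self, fast_params):
        A = matrix_from_pairs([(0, 0)], 2, 2)
        with pytest.raises(ValueError, match="at least 2"):
            global_loocv(A, fast_params)

    def test_rank_bounds(self, tiny_matrix, fast_params):
        result = global_loocv(tiny_matrix, fast_params)
        for r in result.ranks:
            assert 1 <= r.rank <= 1 + r.pool_size

    def test_roc_endpoints(self, tiny_matrix, fast_params):
        result = global_loocv(tiny_matrix, fast_params)
        assert tuple(result.roc[0]) == (0.0, 0.0)
        assert tuple(result.roc[-1]) == (1.0, 1.0)
        assert np.all(np.diff(result.roc, axis=0) >= 0)


class TestKfold:
    def test_k_equal_to_omega_reduces_to_global_loocv(self, monkeypatch):
        A = matrix_from_pairs([(0, 0), (1, 1), (2, 2), (0, 2)], 3, 3)
        # deterministic seed-free scorer isolates the fold bookkeeping
        monkeypatch.setattr(
            ev,
            "holdout_scores",
            lambda A_, held, params: np.arange(A_.M.size, dtype=float).reshape(
                A_.M.shape
            ),
        )
        kf = kfold_cv(A, k=len(A.omega), repeats=1, seed=0)
        assert kf.auc == pytest.approx(global_loocv(A).auc, abs=1e-12)

    def test_fixed_seed_is_reproducible(self, tiny_matrix, fast_params):
        kw = dict(params=fast_params, k=5, repeats=2, seed=123)
        a = kfold_cv(tiny_matrix, **kw)
        b = kfold_cv(tiny_matrix, **kw)
        assert a.per_repeat_aucs == b.per_repeat_aucs
        assert a.ranks == b.ranks

    def test_k_larger_than_omega_rejected(self, fast_params):
        A = matrix_from_pairs([(0, 0), (1, 1)], 2, 2)
        with pytest.raises(ValueError):
            kfold_cv(A, fast_params, k=3)
        with pytest.raises(ValueError):
            kfold_cv(A, fast_params, k=1)

    def test_unknown_pool_rule_rejected(self, tiny_matrix, fast_params):
        with pytest.raises(ValueError, match="pool"):
            kfold_cv(tiny_matrix, fast_params, pool="bogus")

    def test_holdout_hygiene(self, tiny_matrix, fast_params, monkeypatch):
        """Held-out entries are absent from every training matrix."""
        real = ev.holdout_scores
        seen = []

        def spy(A, held, params):
            training = A.without(held)
            for pair in held:
                assert training.M[pair] == 0.0
                assert pair not in training.omega
            seen.append(len(held))
            return real(A, held, params)

        monkeypatch.setattr(ev, "holdout_scores", spy)
        kfold_cv(tiny_matrix, fast_params, k=5, repeats=1, seed=0)
        assert len(seen) == 5
        assert sum(seen) == len(tiny_matrix.omega)

    def test_mean_auc_consistent_with_global_loocv(self, fast_params):
        """Fold-wise holdout agrees with leave-one-out up to the
        learning-curve bias: training on (k-1)/k of the known set can only
        depress the AUC, and at this scale by no more than a small margin."""
        A = simulate(15, 12, 2, 0.2, 0.7, seed=9).observed
        g = global_loocv(A, fast_params).auc
        kf = kfold_cv(A, fast_params, k=5, repeats=10, seed=1)
        se = kf.auc_std / np.sqrt(len(kf.per_repeat_aucs))
        assert kf.auc <= g + 3 * se
        assert kf.auc >= g - 0.1

    def test_training_complement_pool_admits_fold_mates(self, tiny_matrix, fast_params):
        a = kfold_cv(tiny_matrix, fast_params, k=5, repeats=1, seed=0)
        b = kfold_cv(
            tiny_matrix, fast_params, k=5, repeats=1, seed=0,
            pool="training_complement",
        )
        assert all(
            rb.pool_size >= ra.pool_size for ra, rb in zip(a.ranks, b.ranks)
        )
        assert sum(rb.pool_size for rb in b.ranks) > sum(
            ra.pool_size for ra in a.ranks
        )


class TestRankCandidates:
    def test_saturated_column_yields_empty_list(self, fast_params):
        A = matrix_from_pairs([(0, 0), (1, 0), (0, 1)], 2, 2)
        X = svt_complete(A, fast_params).X
        assert rank_candidates(X, A, "d0") == []

    def test_known_associations_excluded_and_order_descending(self):
        A = matrix_from_pairs([(0, 0)], 3, 1)
        X = np.array([[0.9], [0.2], [0.7]])
        ranked = rank_candidates(X, A, "d0")
        assert [(r.rank, r.mirna, r.score) for r in ranked] == [
            (1, "m2", 0.7),
            (2, "m1", 0.2),
        ]

    def test_ties_broken_by_row_index(self):
        A = matrix_from_pairs([(0, 1)], 3, 2)
        X = np.full((3, 2), 0.5)
        ranked = rank_candidates(X, A, "d0")
        assert [r.mirna for r in ranked] == ["m0", "m1", "m2"]

    def test_unknown_disease_rejected(self, tiny_matrix):
        with pytest.raises(ValueError, match="unknown disease"):
            rank_candidates(tiny_matrix.M, tiny_matrix, "no-such-disease")

    def test_n_clamps_to_pool_size(self):
        A = matrix_from_pairs([(0, 0)], 4, 1)
        X = np.arange(4.0).reshape(4, 1)
        assert len(rank_candidates(X, A, "d0", n=50)) == 3
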