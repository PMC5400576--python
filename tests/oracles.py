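"""Independent brute-force oracles the implementation is checked against.

Everything here is written for transparency, not speed: full SVDs,
explicit pair enumeration, plain Python loops. None of it calls back into
the code paths under test beyond re-using the holdout refit to obtain the
same score matrices.
"""

import numpy as np

from mcmda.evaluation import holdout_scores


def shrink_oracle(X, tau):
    """Full SVD, subtract tau from each singular value, clamp at 0, rebuild."""
    U, s, Vt = np.linalg.svd(np.asarray(X, dtype=float), full_matrices=True)
    out = np.zeros_like(X, dtype=float)
    for k in range(len(s)):
        out += max(s[k] - tau, 0.0) * np.outer(U[:, k], Vt[k, :])
    return out


def mann_whitney_auc(test_scores, candidate_scores):
    """U statistic / (n_test * n_candidate) by explicit pair enumeration."""
    wins = 0.0
    for t in test_scores:
        for c in candidate_scores:
            if t > c:
                wins += 1.0
            elif t == c:
                wins += 0.5
    return wins / (len(test_scores) * len(candidate_scores))


def svt_reference(M, mask, tau, delta=1.5, eps=1e-4, maxiter=500):
    """Plain-loop transcription of the Uzawa/SVT iteration (numpy SVD)."""
    M = np.asarray(M, dtype=float)
    Y = np.zeros_like(M)
    norm_M = np.linalg.norm(M[mask])
    X = np.zeros_like(M)
    for k in range(1, maxiter + 1):
        U, s, Vt = np.linalg.svd(Y, full_matrices=False)
        X = (U * np.maximum(s - tau, 0.0)) @ Vt
        if np.linalg.norm(M[mask] - X[mask]) / norm_M < eps:
            return X, k, True
        Y[mask] += delta * (M[mask] - X[mask])
    return X, maxiter, False


def loocv_enumeration(A, params, local):
    """Brute-force LOOCV: every (test, candidate) comparison counted one by one.

    Returns (auc, ranks) where ranks maps each test pair to its mid-rank in
    its pool. Shares the refit (holdout_scores) with the implementation so
    that only the ranking/aggregation arithmetic is independently derived.
    """
    wins = 0.0
    comparisons = 0
    ranks = {}
    for pair in sorted(A.omega):
        i, j = pair
        X = holdout_scores(A, [pair], params)
        s = X[i, j]
        if local:
            cand = [X[r, j] for r in range(A.nm) if (r, j) not in A.omega]
        else:
            cand = [
                X[r, c]
                for r in range(A.nm)
                for c in range(A.nd)
                if (r, c) not in A.omega
            ]
        if not cand:
            continue
        w = sum(1.0 for c in cand if c < s) + 0.5 * sum(1.0 for c in cand if c == s)
        wins += w
        comparisons += len(cand)
        ranks[pair] = 1.0 + (len(cand) - w)
    return wins / comparisons, ranks
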