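"""Cross-validation protocols and ranking-based ROC/AUC.

Three protocols evaluate how well completion scores recover deliberately
hidden known associations:

* **global LOOCV** — each known pair is removed in turn, the matrix is
  re-completed, and the removed pair's score is ranked against every
  candidate pair (pairs with no known association anywhere in the matrix);
* **local LOOCV** — as global, but the removed pair competes only against
  the candidate pairs of its own disease column;
* **repeated k-fold CV** — the known set is randomly partitioned into k
  disjoint folds; each fold is removed as a block and every test pair is
  ranked against the matrix-wide candidate pool.

AUC is the probability that a randomly chosen test pair outscores a
randomly chosen candidate, ties counted one half (the Mann-Whitney
statistic); equivalently the trapezoidal area under the rank-threshold ROC
curve. Test samples keep their own candidate pool, so the protocol AUC is
the pooled win fraction over every (test, candidate) comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import AssociationMatrix, RankedCandidate
from .svt import SVTParams, svt_complete

__all__ = [
    "CVResult",
    "RankRecord",
    "holdout_scores",
    "global_loocv",
    "local_loocv",
    "kfold_cv",
    "roc_auc",
    "rank_candidates",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankRecord:
    """Mid-rank of one held-out pair within its candidate pool."""

    pair: tuple[int, int]
    rank: float  # 1 + losses + ties/2 among {test} + candidates
    pool_size: int  # number of candidates compared against
    wins: float  # candidates strictly below, plus half of the ties


@dataclass(frozen=True)
class CVResult:
    """Outcome of one cross-validation protocol."""

    scheme: str
    ranks: tuple[RankRecord, ...]
    roc: np.ndarray  # (n, 2) array of (FPR, TPR) points
    auc: float
    per_repeat_aucs: tuple[float, ...] = ()
    skipped: tuple[tuple[int, int], ...] = ()

    @property
    def auc_std(self) -> float:
        """Standard deviation of the per-repeat AUCs (k-fold only)."""
        if not self.per_repeat_aucs:
            return 0.0
        return float(np.std(self.per_repeat_aucs))


def _wins_ties(score: float, candidates: np.ndarray) -> tuple[int, int]:
    wins = int(np.count_nonzero(candidates < score))
    ties = int(np.count_nonzero(candidates == score))
    return wins, ties


def _rank_record(pair, score, candidates) -> RankRecord:
    wins, ties = _wins_ties(score, candidates)
    losses = candidates.size - wins - ties
    return RankRecord(
        pair=pair,
        rank=1.0 + losses + ties / 2.0,
        pool_size=int(candidates.size),
        wins=wins + ties / 2.0,
    )


def _pooled_auc(records: Sequence[RankRecord]) -> float:
    """Win fraction pooled over every (test, candidate) comparison."""
    total = sum(r.pool_size for r in records)
    if total == 0:
        raise ValueError("no comparisons: every candidate pool was empty")
    return float(sum(r.wins for r in records) / total)


def _rank_roc(records: Sequence[RankRecord]) -> np.ndarray:
    """ROC over normalized-rank thresholds.

    Each record's loss fraction p = 1 - wins/pool_size is its normalized
    position among the candidates; sweeping a threshold x over [0, 1] gives
    FPR = x (fraction of each pool admitted) and TPR = fraction of test
    samples with p <= x.
    """
    ps = np.sort([1.0 - r.wins / r.pool_size for r in records])
    xs = np.unique(ps)
    n = len(ps)
    points = [(0.0, 0.0)]
    for x in xs:
        points.append((float(x), float(np.count_nonzero(ps <= x) / n)))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return np.array(points)


def roc_auc(
    test_scores: Sequence[float], candidate_scores: Sequence[float]
) -> tuple[np.ndarray, float]:
    """ROC curve and AUC for one shared pool of test and candidate scores.

    Sweeps the score threshold over the pooled unique values: at each
    threshold t, TPR is the fraction of test scores >= t and FPR the
    fraction of candidate scores >= t. Trapezoidal integration makes tied
    blocks diagonal segments, so the area equals the Mann-Whitney statistic
    with ties counted one half.
    """
    tests = np.asarray(test_scores, dtype=float)
    cands = np.asarray(candidate_scores, dtype=float)
    if tests.size == 0 or cands.size == 0:
        raise ValueError("test and candidate score lists must be non-empty")
    thresholds = np.unique(np.concatenate([tests, cands]))[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        tpr.append(float(np.count_nonzero(tests >= t) / tests.size))
        fpr.append(float(np.count_nonzero(cands >= t) / cands.size))
    roc = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(roc[:, 1], roc[:, 0]))
    return roc, auc


def holdout_scores(
    A: AssociationMatrix,
    held_out: Iterable[tuple[int, int]],
    params: SVTParams | None = None,
) -> np.ndarray:
    """Score matrix completed with ``held_out`` entries removed from training.

    The held-out entries are set to 0 and dropped from omega on a copy;
    ``A`` itself is never modified. ``held_out`` must be a subset of
    ``A.omega``.
    """
    held_out = frozenset(held_out)
    training = A.without(held_out)  # raises on held_out not in omega
    return svt_complete(training, params).X


def _candidate_mask(A: AssociationMatrix) -> np.ndarray:
    """Mask of candidate pairs: no known association anywhere in A."""
    return ~A.omega_mask


def _loocv(A: AssociationMatrix, params: SVTParams | None, local: bool) -> CVResult:
    if len(A.omega) < 2:
        raise ValueError("LOOCV needs at least 2 known associations")
    candidates = _candidate_mask(A)
    records = []
    skipped = []
    for pair in sorted(A.omega):
        i, j = pair
        if local and not candidates[:, j].any():
            logger.warning(
                "local LOOCV: disease column %d has no candidate pairs; "
                "test sample %s skipped",
                j,
                pair,
            )
            skipped.append(pair)
            continue
        X = holdout_scores(A, [pair], params)
        pool = X[:, j][candidates[:, j]] if local else X[candidates]
        records.append(_rank_record(pair, X[i, j], pool))
    return CVResult(
        scheme="local_loocv" if local else "global_loocv",
        ranks=tuple(records),
        roc=_rank_roc(records),
        auc=_pooled_auc(records),
        skipped=tuple(skipped),
    )


def global_loocv(A: AssociationMatrix, params: SVTParams | None = None) -> CVResult:
    """Leave-one-out CV ranking each held-out pair against all candidate pairs."""
    return _loocv(A, params, local=False)


def local_loocv(A: AssociationMatrix, params: SVTParams | None = None) -> CVResult:
    """Leave-one-out CV ranking each held-out pair within its disease column.

    A test pair whose disease column has no candidate pairs is skipped with
    a warning and reported in ``CVResult.skipped``.
    """
    return _loocv(A, params, local=True)


def kfold_cv(
    A: AssociationMatrix,
    params: SVTParams | None = None,
    k: int = 5,
    repeats: int = 100,
    seed: int = 0,
    pool: str = "full_complement",
) -> CVResult:
    """Repeated k-fold CV over the known associations.

    Per repeat r the known set is shuffled with seed ``seed + r`` and split
    into k disjoint folds; each fold is held out as a block and every test
    pair in it is ranked against the candidate pool. With the default
    ``pool="full_complement"`` candidates are the pairs outside the full
    known set, so same-fold test pairs never count as candidates;
    ``pool="training_complement"`` additionally admits them. The reported
    AUC is the mean over repeats, with per-repeat values retained.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if len(A.omega) < k:
        raise ValueError(f"k={k} exceeds the {len(A.omega)} known associations")
    if pool not in ("full_complement", "training_complement"):
        raise ValueError(f"unknown candidate pool rule {pool!r}")
    omega = sorted(A.omega)
    full_candidates = _candidate_mask(A)
    all_records: list[RankRecord] = []
    per_repeat = []
    for r in range(repeats):
        rng = np.random.default_rng(seed + r)
        order = rng.permutation(len(omega))
        folds = np.array_split(order, k)
        repeat_records = []
        for fold in folds:
            held = [omega[idx] for idx in fold]
            X = holdout_scores(A, held, params)
            for pair in held:
                i, j = pair
                if pool == "full_complement":
                    cand = X[full_candidates]
                else:
                    mask = full_candidates.copy()
                    for other in held:
                        if other != pair:
                            mask[other] = True
                    cand = X[mask]
                repeat_records.append(_rank_record(pair, X[i, j], cand))
        per_repeat.append(_pooled_auc(repeat_records))
        all_records.extend(repeat_records)
    return CVResult(
        scheme="kfold",
        ranks=tuple(all_records),
        roc=_rank_roc(all_records),
        auc=float(np.mean(per_repeat)),
        per_repeat_aucs=tuple(per_repeat),
    )


def rank_candidates(
    X: np.ndarray, A: AssociationMatrix, disease: str, n: int | None = None
) -> list[RankedCandidate]:
    """Rank the unknown miRNAs of one disease by descending completion score.

    miRNAs already known to associate with the disease are excluded. Ties
    are broken by miRNA first-occurrence (row) index, so the ordering is
    deterministic. ``n`` truncates to the top n (clamped to the pool size).
    """
    try:
        j = A.disease_index(disease)
    except KeyError:
        raise ValueError(f"unknown disease name {disease!r}") from None
    X = np.asarray(X, dtype=float)
    if X.shape != A.M.shape:
        raise ValueError(f"score matrix shape {X.shape} != adjacency {A.M.shape}")
    rows = [i for i in range(A.nm) if (i, j) not in A.omega]
    rows.sort(key=lambda i: (-X[i, j], i))
    if n is not None:
        rows = rows[: max(n, 0)]
    return [
        RankedCandidate(rank=r, mirna=A.mirna_names[i], disease=disease, score=float(X[i, j]))
        for r, i in enumerate(rows, start=1)
    ]
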