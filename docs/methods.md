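# Methods

## Model and algorithm

The known miRNA–disease associations form a binary adjacency matrix
*M* ∈ {0,1}^(nm×nd) with observed set Ω = {(i,j): M(i,j)=1}. Only positive
links are curated, so every 0 is "unlabeled", not "negative". The working
assumption is that the true association matrix is approximately low rank:
diseases share miRNA programs and miRNAs act on families of diseases, so a
few latent factors explain most links. Under that assumption the scores of
the unlabeled pairs are recovered by nuclear-norm-regularized matrix
completion,

    min_X  τ‖X‖* + ½‖X‖²_F    s.t.  P_Ω(X) = P_Ω(M),

whose Lagrangian saddle point is found by Uzawa's iteration. Each step
applies the singular value shrinkage operator D_τ (the proximal operator of
τ‖·‖\*: SVD, subtract τ from each singular value, clamp at zero,
reconstruct) to the dual iterate, then updates the dual by the constraint
residual on Ω:

    X_k = D_τ(Y_{k-1}),
    Y_k = Y_{k-1} + δ · P_Ω(M − X_k),    Y_0 = 0.

The iteration stops when ‖P_Ω(M − X_k)‖_F < ε‖P_Ω(M)‖_F or at `maxiter`.
Because Y_0 = 0 and the update is Ω-supported, Y stays zero off Ω
throughout — the dual multiplier only acts on the observed constraints.
The completed matrix X_n is used for ranking only: scores are not clipped
to [0,1] and carry no probabilistic meaning.

## Parameters

| parameter | default | meaning |
|---|---|---|
| τ | 5·√(nm·nd) | singular-value shrinkage threshold; larger values bias toward lower rank |
| δ | 1.5 | Uzawa step size; the dual ascent converges for 0 < δ < 2 |
| ε | 10⁻⁴ | relative Frobenius stopping tolerance on Ω |
| maxiter | 500 | iteration cap; hitting it is a warning, not an error |

The τ default follows the standard SVT recommendation for an nm×nd
problem. The alternative product reading τ = 5·nm·nd is exposed as
`tau_rule="product"` for comparison runs, but it exceeds the largest
singular value of any 0/1 matrix of that shape (σ₁ ≤ √(nm·nd)), so it
shrinks every iterate to zero and is never the default.

Non-convergence at the cap is deliberate behaviour, not failure: at desk
scale (matrices up to ~80×60) the default τ is large relative to σ₁(M), the
dual matrix must grow for tens of iterations before any singular value
clears the threshold, and the 10⁻⁴ tolerance is typically not reached
within 500 iterations (residuals land near 10⁻²–10⁻³). The capped iterate
is still an excellent ranking score — empirically it separates hidden true
links from true non-links *more* strongly than a small-τ converged run,
because heavier shrinkage enforces a lower-rank, more structured solution.
Diagnostics (`iterations`, `converged`, `final_residual`) are always
reported and written into run provenance.

## Evaluation protocols

* **Global LOOCV** — each known link is removed in turn, the matrix is
  re-completed from the remaining links (a full refit per test sample; no
  information from the held-out entry reaches training), and the held-out
  pair's score is compared with every *candidate* pair (pairs with no known
  association anywhere in the matrix).
* **Local LOOCV** — identical refits, but the held-out pair competes only
  against the candidate pairs of its own disease column. A column with no
  candidates skips its test samples with a warning; skips are reported, not
  silently dropped.
* **Repeated 5-fold CV** — the known set is shuffled (seed + repeat index)
  and split into five disjoint folds; each fold is removed as a block and
  each of its pairs is ranked against the matrix-wide candidate pool.
  Candidates are the complement of the *full* known set, so same-fold test
  pairs are never counted as candidates (`pool="training_complement"`
  switches to the alternative). The reported AUC is the mean over repeats
  with its standard deviation.

AUC is the Mann–Whitney statistic: the probability that a random test
sample outscores a random candidate, ties counted one half. For a single
shared pool this equals trapezoidal integration of the rank-threshold ROC
curve (tied blocks become diagonal segments); for the protocols, where each
test sample keeps its own candidate pool, the AUC is the win fraction
pooled over every (test, candidate) comparison, and the reported ROC sweeps
a normalized-rank threshold. Ranks are mid-ranks throughout, so duplicated
scores are handled identically everywhere. Per-disease candidate rankings
break ties by miRNA first-occurrence index, making all outputs
deterministic.

A `--no-refit`-style shortcut (scoring all held-out entries from a single
completion) is intentionally absent from the protocols: completing with the
test entry present leaks label information into its own score.

## Synthetic data generator

The generator makes the low-rank premise literal: non-negative latent
factors L ∈ R^(nm×r), R ∈ R^(r×nd) are drawn i.i.d. uniform, and the top
`round(density·nm·nd)` entries of L·R become the 1-entries of the binary
truth (quantile thresholding, deterministic tie-break by flat index; the
measure-zero case of a tie at the threshold triggers one logged
regeneration). A uniform sample of `floor(count·fraction)` (minimum 1) of
the 1-entries becomes the observed association list; the hidden 1-entries
are the recovery targets. Everything is deterministic given the seed.

What this emulates: a sparse binary bipartite adjacency of approximately
low rank with an incomplete positive-only sample — the structural premise
of the method. What it does not emulate: the heavy-tailed degree
distributions of real curated databases (hub miRNAs such as mir-21,
intensively studied diseases), curation bias (well-studied pairs are
observed preferentially, not uniformly), name-level noise, or any
similarity structure beyond low rank. Passing tests therefore demonstrate
correctness of the algorithmic machinery and recoverability under the
model's own assumptions, not performance on real curated data.

Default study conditions in the acceptance script — 60×40, rank 3, 10%
density, 70% of links observed, and a 40×40 rank-2 grid over observed
fractions {0.3, 0.5, 0.7} — were chosen once as a desk-scale analogue of a
curated database that keeps the per-sample LOOCV refit affordable
(hundreds of refits × up to 500 dense SVDs each run in well under a minute).

## Numerical choices

* Dense SVD (LAPACK via scipy) each iteration; at adjacency scale
  (hundreds × hundreds) a truncated SVD buys nothing. The SVD call is an
  injection seam (`shrink(..., svd=...)`) so a partial-SVD backend can be
  swapped in.
* Shrinkage reconstruction is invariant to SVD sign/rotation ambiguity;
  tests assert backend agreement at 1e-8 Frobenius and oracle agreement of
  the shrinkage operator at the same tolerance; iteration equivalence
  against a plain-loop reference is asserted at 1e-6.
* An empty Ω (no known associations) makes the relative stopping criterion
  undefined; the solver raises a degenerate-input error instead of
  returning zeros.
* Per-iterate residuals of the Uzawa dual ascent are not monotone, so no
  per-iteration decrease is asserted anywhere; convergence is asserted only
  on well-conditioned instances with a threshold small enough for the
  tolerance to be reachable within the cap.

## Known limitations and observed behaviour

* Diseases with no known miRNA (empty columns) and miRNAs with no known
  disease get identical (zero-information) scores: the method cannot rank
  for entities absent from the training matrix.
* 5-fold CV trains on 4/5 of the known set while LOOCV trains on all but
  one link, so at small scale the 5-fold AUC sits systematically a few
  points below the LOOCV AUC — a learning-curve bias, not partition noise
  (it exceeds three standard errors of the repeat distribution at every
  desk scale measured). The consistency test asserts the one-sided
  property: 5-fold AUC ≤ LOOCV AUC + 3·SE and within 0.1 below it. The gap
  shrinks as the known set grows.
* The number of repeats behind a reported k-fold mean ± SD is a free
  choice (default 100 in the API, 20 in the acceptance script); the ± value
  is the standard deviation across repeats.
* Whether real curated matrices are close enough to low rank for these
  guarantees to transfer is an empirical question outside the synthetic
  tests' reach; the CLI runs end-to-end on any user-supplied association
  list for exactly that purpose.
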