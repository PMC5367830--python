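# Methods

This note documents the models, estimators, and numerical choices behind
the package, what the synthetic data does and does not emulate, and the
known limitations.

## Scoring functions and the WD kernel

All methods operate on a *scorer*: a deterministic map s: Σ^L → ℝ over
the DNA alphabet Σ = {A,C,G,T}, exposed through a minimal contract
(callable on strings, optionally batch/vectorized).  Any trained
classifier can be wrapped; nothing below assumes differentiability or
access to internals.

The reference scorer is a soft-margin SVM with the weighted-degree (WD)
string kernel

κ(x, x′) = Σ_{ℓ=1..ℓmax} Σ_{j=1..L−ℓ+1} 1{x[j]^ℓ = x′[j]^ℓ},

an unweighted sum over degrees (per-degree weights β_ℓ are available
behind a flag and default to 1).  Training solves the standard dual on a
precomputed Gram matrix (libsvm backend), with an 80/20 train/test split
driven by the dataset seed; `max_train` caps the Gram size on large
datasets.  Because the kernel's feature map is the indicator of every
positional oligomer, the scoring function collapses to
s(x) = Σ_ℓ Σ_j w(x[j]^ℓ, j) + b, and the weight table w is materialized
explicitly (dense per-length arrays) at training time.  Scoring is then
O(ℓmax·L) per sequence; the kernel-expansion evaluation is retained as
an independent path and must agree with the table to 1e-8 (tested).
The bias b is excluded from the table but added to every score; it
shifts all conditional expectations equally and cancels under centering.

Defaults: ℓmax = 8 and C = 1 (the settings used for all reference
experiments).

## gPOIM: sampled positional-oligomer importances

The model-based importance of k-mer y at position j is the centered
conditional expectation S_{k,y,j} = E[s(X) | X[j]^k = y] − E[s(X)] under
a uniform i.i.d. background X (a hook accepts user-supplied background
samplers).  The estimator draws one pool of n sequences, scores each
once, and assigns its score to bin (z[j]^k, j) for every window j; each
entry is the bin mean.  Consequences, all tested:

- per column, bin counts partition the pool, and the count-weighted mean
  of bin values equals the pool mean (conservation);
- empty bins are *missing* (NaN), never zero — a zero would fabricate
  importance; downstream consumers skip missing entries;
- the estimator converges to the exact conditional expectation at the
  Monte-Carlo rate O(1/√n); feeding the full enumeration of Σ^L through
  the binning machinery reproduces the exact matrix to 1e-8.

Instance-based explanations reuse the same machinery: for a sequence g,
the importance of window i is the uncentered bin value at (g[i]^k, i)
minus the pool mean, and per-position scores average all windows
covering a position (window-start-only aggregation is available).  The
default explanation order is ℓmax − 2 capped at 6 for WD models, 3 for
generic scorers.

For WD-SVMs the same quantity is computed exactly from the weight
table: a stored weight w(z, i) of length ℓ contributes
w(z,i)·P(X[i]^ℓ = z | X[j]^k = y), which is 0 on a letter conflict and
(1/4)^(free positions) otherwise; non-overlapping terms cancel under
centering.  The computation is vectorized per (ℓ, i, j) by marginalizing
the dense weight array onto the overlap letters, and is guarded to
4^k·(L−k+1) ≤ 10^7 entries.  Orders above the kernel degree are valid
and supported.

Pool sizes: 1,000 samples suffice for low orders (k ≤ 2) in the sense
that the max-abs error is already dominated by per-bin noise ~1/√(n/4^k);
matrices used for *motif fitting* should have every bin populated, so
order-4 fits use the 10,000-sample pool (4^4 = 256 bins per column,
≈ 39 samples each).  A pool with n < 4^k triggers a warning.  On
normalized matrices (centered, unit max-abs entry) the Frobenius
distance between a 1,000-sample order-2 estimate and the exact matrix
is O(10^-1)·√(#cells) — the acceptance script reports the measured
value; convergence claims in the test suite are therefore stated as the
rate and the enumeration limit rather than an absolute threshold, since
any absolute number is an artifact of the normalization convention.

## Differential POIM and locus estimation

With q_max^{l,j} = max_y |Q_{l,y,j}| (missing entries skipped), the
differential POIM is

Ω_{l,j} = q_max^{l,j} − max(q_max^{l−1,j}, q_max^{l−1,j+1}) for l ≥ 2,
else 0.

A motif of length l₀ ≤ k_max concentrates in the single cell (l₀, start).
A motif *longer* than k_max instead saturates a contiguous run of cells
at l = k_max spanning its interior: every in-motif start position gains
importance over its (l−1)-mer sub-patterns.  The locus estimator
exploits this: it repeatedly takes the largest remaining cell (ties
toward smaller position, then smaller length), expands it left and right
over contiguous cells at the same order with Ω ≥ 50% of the peak, and
calls the locus (block start, block width + l − 1) — recovering both
position and length even for motifs several times longer than k_max
(verified for a 50-mer at k_max = 8).  Candidates whose span overlaps an
accepted locus by more than half the shorter length are suppressed, and
calling stops after `max_motifs` or when the next peak falls below 5% of
the first.  The block fraction, overlap fraction, and stopping floor are
configurable; the defaults were chosen for determinism and conservatism,
not tuned per dataset.

## Convex motifPOIM: PWM fitting

A probabilistic positional motif is m = (r, μ) with r ∈ ℝ^{4×k}
column-stochastic.  Its weight for k-mer z is v_z(r) = Π_ℓ r_{z_ℓ,ℓ},
and the reconstruction at matrix column i uses the SubPPM window of r
starting at offset i − μ.  The environment U(μ) = [μ, …, μ+k−1] includes
every start position inside the motif; windows running past the motif
end are right-truncated and padded with the uniform background (a factor
1/4 per uncovered position), so each window's weights still sum to 1.
The padding matters: without it a motif cannot explain the importance of
its own suffix k-mers, and when two motifs overlap that unexplained
signal leaks into the other motif's environment and corrupts its fit.
A `complete`-windows environment (offsets 0..k−k̃ only) is available as
an option.

The objective is
f = ½ Σ_{z,i} (R_{z,i} − (S_{z,i} + c·1{i ∈ U}))² summed over defined S
entries only, with offset c = max(0, 1 − min S) so that S + c ≥ 1
everywhere.  Since every in-environment column of R sums to a constant
on the feasible set, the c-term contributes only an additive constant:
the minimizer is invariant to c.  This contract is tested to 1e-4 in
the PWM entries across c, c+1, c+10.

On convexity: f is a convex quadratic in the induced weight vectors v
and convex in each PWM column separately, but it is *not* jointly convex
in the PWM entries — v is multilinear, the set of product-form weight
vectors is non-convex, and no offset changes this (the c-term is
constant on the feasible set).  Midpoint-convexity checks on random
feasible PWM pairs exhibit violations of order 10^-2 to 10^-1, and the
acceptance suite reports this honestly.  What holds in practice, and
what the suite verifies instead, is that the landscape is benign:
uniform and ten random-simplex initializations reach objectives within
1e-6 and identical motifs on all reference problems.

Solver: projected gradient descent with analytic gradients
(prefix/suffix product trick per window), exact Euclidean projection of
every column onto the probability simplex (sort-based), and Armijo
backtracking (σ = 1e-4, β = 0.5) guaranteeing a monotone objective
trace.  The step is re-expanded after each accepted iteration.  Stopping:
relative objective change below 1e-14 or 10,000 iterations.  The
tolerance is deliberately tight — iterations cost microseconds at these
problem sizes, and a looser stop leaves the iterate far enough from the
optimum to blur the offset-invariance contract when the optimum is
interior (sampled, noisy matrices).  Typical fits converge in 10–100
iterations.

Fitting against sampled matrices: missing bins are excluded from the
objective and gradient, which is correct for occasional gaps but
degenerate when a large fraction of bins is empty — probability mass
can then hide on unobserved k-mers at zero cost, and the invariance
argument fails because the defined-cell mass sum is no longer constant.
The practical rule, used by all shipped experiments: choose k̃ so the
pool populates all 4^k̃ bins (k̃ = 4 at n = 10,000), or use the exact
matrix (k̃ = 6 by default, within the enumeration guard).  Multiple
motifs per locus (T > 1) are supported through the summed
reconstruction; loci shorter than k̃ are rejected.

## Synthetic data

`generate_dataset(n, L, motifs, positive_fraction, mutation_rate, seed)`
draws i.i.d. uniform sequences; exactly round(n·positive_fraction) of
them are labeled +1 (SVM convention ±1) and carry every motif at its
fixed 1-based position — exact strings verbatim, PWM motifs sampled
column-wise.  Each planted nucleotide is then independently redrawn
uniformly with probability `mutation_rate`, so the effective mismatch
rate is 3p/4 (a redraw restores the original with probability 1/4); the
tests check this rate to three standard errors.  Datasets are byte-
reproducible from the seed.  For experiments where different positive
subpopulations carry different (e.g. mutually exclusive, overlapping)
motifs, subpopulations are generated separately and concatenated with a
reshuffle.

What the generator does *not* emulate: non-uniform or Markov
backgrounds, positional jitter of motifs, variable-length sequences,
composition bias, or correlated noise.  Passing tests therefore
demonstrate correctness of the estimators and the optimizer under the
model's own assumptions (localized motifs, uniform background) — not
robustness to the full messiness of genomic data, where background
composition and motif mobility can dilute positional importance.

## Reference experiment sizes

The acceptance script and test suite run the controlled experiments at
these sizes (chosen so the full suite runs in about a minute while every
recovery result is stable across seeds):

- two-motif accuracy: 10,000 generated sequences (positive quarter
  carries GGCCGTAAA@11 and TTTCACGTTGA@24, L = 40), degree-8 SVM trained
  on a 3,000-sequence subsample, mean held-out accuracy over 5 seeds;
- single-motif reference (CCTATA@11, L = 30): 2,000 sequences, at
  mutation 0 and 0.3;
- long motif (TGGCCGTAAA×5 at 10, L = 100): 10,000 sequences, Gram on
  2,500;
- overlapping motifs (TGGCCGGAAA@11, TTCCCGTTGACAT@16, L = 30): 1,000
  sequences, 125 positives per motif;
- sampling-rate checks: L = 8, ℓmax = 3 toy SVM, exhaustively
  enumerable (4^8 sequences).

## Known limitations

- Sequences must share one length L; motifs are assumed localized
  (fixed position, fixed shape).
- The exact importance oracle exists only for WD-SVM scorers; for other
  models only the sampled estimator applies.
- Importance matrices grow as 4^k: orders beyond ~8 are impractical to
  store, and sampled matrices need pools ≫ 4^k per-column bins.
- The fit optimum is analyzed as if unique; on symmetric or
  signal-free inputs (e.g. an all-zero importance matrix) multiple
  minimizers exist and the solver returns one of them deterministically
  from its initialization.
- Mutation noise above ~2/3 makes the planted motif no more likely than
  random background, and recovery necessarily degrades.
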