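# Methods

## Segmentation model and losses

A series `y_1..y_n` of non-negative integers is modelled as independent and
piecewise identically distributed: `K − 1` change-points split `[1, n]` into
segments, each with its own parameter `θ_r`, under one of three losses
(negative log-likelihood up to terms free of `θ`):

| family   | `γ(y, θ)`                    | `θ` space | segment minimizer        |
|----------|------------------------------|-----------|--------------------------|
| nbinom   | `−φ log θ − y log(1−θ)`      | (0, 1)    | `d1/(d1+d2)`, `d1=φ·n_r`, `d2=Σy` |
| poisson  | `θ − y log θ`                | (0, ∞)    | segment mean             |
| gaussian | `(y − θ)²`                   | ℝ         | segment mean             |

The negative binomial uses the exponential-family success-probability
parametrization (`E(Y) = φ(1−θ)/θ`, `Var = φ(1−θ)/θ²`); `φ` is a single
global dispersion shared by all segments.  Because the additive constant
`A(φ, y)` is dropped, costs are comparable across segmentations of the same
series at a fixed `φ`, but not across different `φ`.  A segment's cost
function is held as two (three for Gaussian) running coefficients, updated
in O(1) per appended point.

Degenerate segments (all zeros under nbinom: minimizer at the boundary
`θ → 1`) are handled by clipping parameters into `[ε, 1−ε]` with
`ε = 1e−12`; this perturbs costs by O(n·φ·ε), far below every tolerance
used.  The same clip is applied wherever the plug-in fit `θ_r = φ/(φ+ȳ_r)`
is evaluated (criterion cost, Hellinger profiles).

## The pruned DP sweep

For each level `k` the sweep maintains a list of candidate last
change-points `τ`, each carrying its constant `C(k−1, τ)`, its running
segment-cost coefficients, and a **live set**: the interval of `θ` values on
which the candidate is not yet dominated.  At each new position `t`:

1. the point is folded into every candidate's accumulator;
2. `C(k, t)` is the minimum over candidates of the candidate's cost
   minimized over its live set (convexity: evaluate at the clipped
   unconstrained minimizer);
3. each candidate's live set is intersected with its level set
   `{θ : H_τ(θ) ≤ C(k−1, t)}` — the set where it still beats the entering
   candidate `τ = t`, whose cost function is that constant — and candidates
   with empty live sets are removed permanently;
4. the entering candidate receives the part of the parameter space not
   covered by the survivors.

Level sets of the count losses are found by bisection on each side of the
minimizer (absolute tolerance `1e−9` in `θ`, 200-iteration cap; the upper
bracket for the unbounded Poisson space by geometric expansion); the
Gaussian case is a quadratic solved in closed form.

**Live sets are single intervals.**  The uncovered region in step 4 can in
principle be a union of intervals; the implementation assigns its interval
hull.  This may make live sets overlap and pruning conservative, but never
makes costs wrong: every `θ` stays covered by some candidate, every
(candidate, `θ`) pair evaluates to the cost of a real segmentation, so the
running minimum is exact.  Consequently the instrumented invariant checked
in the tests is *coverage* of the parameter space (no gaps at any sweep
step), not disjointness.  Exactness itself is enforced against an unpruned
O(K·n²) dynamic program over precomputed single-segment costs, on all three
families.

Ties among candidates within `1e−10` relative cost are resolved toward the
smallest `τ`, making backtracking deterministic.  The full `C(k, t)` and
argmin matrices are kept (O(Kmax·n) memory), which makes traceback for
every `k` and the constrained-breakpoint query cheap.

The production path is a numba-compiled kernel; an instrumentable
pure-Python sweep with identical semantics backs the property tests and the
live-set diagnostics.  The two are pinned together by the oracle tests.

**Constrained query.**  The cost of the best `K`-segmentation with its
`j`-th change-point at `t` decomposes as the forward cost `C(j, t)` plus
the cost of segmenting the reversed tail into `K − j` segments; minimizing
over `t` recovers the unconstrained optimum, which the tests assert.

**Default `Kmax`** is `floor(√m)` of the effective (compressed) length — a
deliberately generous ceiling for the oracle criterion's calibration range
while keeping the sweep near-linear; it is a free parameter everywhere.

## Plateau compression

Maximal runs of equal values are run-length encoded into weighted points.
For point-additive convex losses, a change-point strictly inside a plateau
can always be moved to a plateau edge without increasing the cost, so
optimal *costs* are invariant (optimal breakpoints need not be identical —
the tests compare costs, not breakpoints; when a breakpoint falls in a
plateau the compressed solution reports the run end).  Compression is
applied by default for all families and is the dominant speed lever on
zero-heavy coverage.  Breakpoints are lifted back to original coordinates
as run ends (1-based inclusive convention; BED output converts to 0-based
half-open).

## Dispersion estimation

`φ` is estimated as the median of the moment estimator
`mean²/(variance − mean)` (unbiased variance) over all stride-1 windows of
width `h`, starting at `h = 15` and doubling while the median is
non-positive or undefined; beyond `h > n/2` the whole-series moment
estimate is the fallback, and a non-positive fallback raises an error
asking the user to supply `φ`.  Non-finite window estimates are excluded
from the median.  Windows straddling change-points are deliberately kept:
the median absorbs them.  On simulated alternating profiles
(n = 10⁴, K = 20) the median of `φ̂/φ` stays within [0.7, 1.3] for both
`φ = 0.3` and `φ = 2.3`, and — the operationally relevant property —
segmentation quality with `φ̂` is indistinguishable from using the true `φ`
(mean Rand-index difference below 0.01 over 100 replicates).

## Model selection

The oracle criterion selects
`K̂ = argmin_K C(K, n) + β·K·(1 + 4√(1.1 + log(n/K)))²` (natural log).  The
cost term equals the plug-in criterion cost because `φ/(φ+ȳ_r)` *is* the
exact segment minimizer — an identity the tests verify numerically.  `β` is
calibrated by the slope heuristic in its simplest published variant: a
least-squares fit of cost against penalty shape on the top half of the `K`
range (the post-true-`K` regime where the cost decays roughly linearly in
the shape), `β = 2·|slope|`, with a Theil–Sen fallback when the fitted
slope is non-negative and an error when no decreasing trend exists at all.
AIC (`cost + D_K`) and BIC (`cost + (D_K/2)·log n`) conveniences use model
dimension `D_K = 2K − 1` (`K` parameters plus `K − 1` breakpoints); their
exact forms are this package's choice.

## Evaluation metrics

**Rand index.**  For labelings `C` (truth) and `Ĉ` of positions into
segments, the index sums agreement over position pairs `(s, t)` with
`t ≥ s + 2` — adjacent pairs are excluded — normalized by `(n−1)(n−2)/2`
pairs; identical labelings score exactly 1 under this pair set (with *all*
pairs the stated normalization would exceed 1).  Computed in O(n) from run
lengths of the two labelings and their refinement; equivalence with the
explicit O(n²) pair sum is tested by enumeration.

**Hellinger.**  Two segmentations of the same profile are compared by
fitting `θ_r = φ/(φ+ȳ_r)` on each side's segments and averaging, over
positions, the Hellinger distance between the two fitted NB distributions.
The Bhattacharyya coefficient has the closed form
`BC = [√(θ1θ2) / (1 − √((1−θ1)(1−θ2)))]^φ` (sum the generating series of
the NB pmf), `H = √(1 − BC)`; it is verified against truncated pmf
summation to 1e−8.

## Synthetic data

The generator draws `K − 1` breakpoints uniformly among compositions of `n`
into `K` parts of length ≥ 5, then samples each segment from NB(φ, θ) with
`θ` alternating 0.8 (odd segments, low signal) / 0.2 (even segments, high
signal) via the gamma–Poisson mixture (exact for non-integer `φ`).
Reference dispersions 0.3 (highly dispersed coverage) and 2.3 (moderately
dispersed) are used throughout the test bench.  The benchmark configuration
is n = 1000 with K = 10 and `Kmax = 31 = floor(√n)` — sizes chosen so the
full 100-replicate study runs in about a minute while leaving segment
lengths (minimum 5, mean 100) in the regime where the windowed dispersion
estimator and the slope heuristic operate as intended.  What the generator
does *not* emulate: positional/GC bias within transcripts, read-level
autocorrelation introduced by fragment length, mappability artefacts, or
multi-sample structure.  Passing tests therefore demonstrate correctness of
the optimization and calibration machinery under the stated model, not
robustness to those real-data effects (upstream normalization is the
intended remedy for bias).

## Known limitations

- The min-over-replicates Rand benchmark is an order statistic: a single
  over-selected replicate (one spurious split of a long homogeneous
  segment, costing ~0.08 of Rand) can dominate it.  Typical values are
  ≥ 0.95; the median is ≥ 0.99.
- The optional per-segment parameter penalty `g(θ)` is not implemented; the
  accumulator's offset slot leaves room for it.
- No heteroscedastic/variance-segmentation losses; no PELT-style
  penalized-path pruning (the segment-number path `k ≤ Kmax` is always
  computed in full).
- bedGraph input assumes one chromosome per run and fills coverage gaps
  with zeros; BAM pileup is out of scope (use `samtools depth`/`bedtools
  genomecov` upstream).
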