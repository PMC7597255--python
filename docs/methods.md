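# Methods

## Model and estimators

The package measures Wiener-type directed dependency between stationary
processes by conditional transfer entropy (CTE),
`I(Y_n; X_n^- | Y_n^-, Z_n^-)`, with the infinite pasts replaced by a
non-uniformly selected set of lagged variables. All information quantities
are differential (continuous-valued data) and reported in nats.

**KSG estimators.** Mutual information uses the Kraskov–Stögbauer–Grassberger
algorithm-1 construction: neighbor ranking under the max norm in the joint
space, the distance `ε_i` to the `T`-th nearest neighbor, strict-inequality
range counts in the marginal spaces, and the digamma correction
`ψ(T) + ψ(N) − ⟨ψ(n_x+1) + ψ(n_y+1)⟩`. Conditional MI uses the
Frenzel–Pompe form `ψ(T) − ⟨ψ(n_xz+1) + ψ(n_yz+1) − ψ(n_z+1)⟩`. With an
empty conditioning block the z-marginal count equals the full allowed sample
count, so the conditional form reduces *algebraically* to the MI form; the
implementation exploits this to give bit-identical values, which is also a
tested invariant. KSG estimates carry a small negative-bias floor and may
dip below zero for (conditionally) independent data; nothing downstream
assumes non-negativity. Estimates were validated against closed-form
Gaussian values (log-determinant identities) and against an independent
brute-force implementation; on bivariate Gaussians at `N = 2000, T = 10`
the estimator is indistinguishable from scikit-learn's KSG to four decimals.

**Nearest-neighbor prediction (MSR).** The target's present is predicted by
the mean of its values at the `T` nearest rows of the candidate realization
matrix (Euclidean metric). The mean squared residual (MSR) of this
regression is the prediction-accuracy statistic used both for ranking
(weighted against CMI by `λ ∈ [0,1]`) and for termination. Because all
channels are standardized, MSR lives on a `[0, ~1]` scale (1 ≈ the target's
own variance) and is commensurable with `γ`.

**KDE regression and AIC.** The AIC-terminated variant predicts the target
by Gaussian-kernel (Nadaraya–Watson) regression with Mahalanobis distance —
coordinates whitened by the sample covariance, diagonal-regularized by
`1e-8 · tr(Σ)/k` when near-singular — and the Gaussian reference bandwidth
`h = (4/(k+2))^{1/(k+4)} N^{−1/(k+4)}`. The complexity `p` is the trace of
the self-inclusive smoother matrix, `Σ_i K(u_i,u_i)/Σ_j K(u_i,u_j)`
(1 when all points coincide, N when all are isolated), and
`AIC = N log(MSE) + 2p`.

## Algorithmic conventions the method description leaves open

These choices are deliberate and documented because the original
formulation underdetermines them; each is exercised by tests.

- **Leave-one-out everywhere.** The query point is excluded from its own
  neighbor list in the MSR regression and from KSG neighbor searches, and
  the KDE prediction removes the query's own kernel mass (while `p` keeps
  the printed self-inclusive form). For the KDE this is load-bearing: a
  self-inclusive average interpolates as the embedding dimension grows, the
  residuals collapse faster than `2p` rises, and the AIC stop never fires
  on some targets. Leave-one-out also makes the degenerate single-sample
  AIC case well-defined (prediction falls back to 0, the standardized
  mean).
- **AIC direction.** The acceptance rule keeps a candidate while the AIC
  *decreases* (better fit-complexity trade-off). The literal
  include-on-increase reading is available via
  `NUEConfig(aic_literal_direction=True)`; it rewards worse trade-offs and
  can run away once the AIC starts climbing.
- **First iteration.** The `msr` and `aic` variants always keep the first
  winner (the improvement test needs a predecessor); the shuffle-terminated
  variants may reject it and return an empty embedding.
- **Tie-breaking and jitter.** Argmax ties resolve to the earlier candidate
  in process-major, lag-minor pool order. Before any neighbor search every
  column receives a deterministic, seeded uniform jitter of amplitude
  `1e-10 ×` its standard deviation: exact distance ties break KSG counts,
  and the jitter makes runs reproducible bit-for-bit given
  `(data, config, seed)`. Neighbor ranking ties resolve lexicographically
  by (distance, row index).
- **Standardization.** All channels (not only targets) are standardized to
  zero mean and unit *population* variance before the search, so the
  `λ`-mixing of CMI (nats) and MSR (variance units) is scale-consistent for
  every candidate.
- **Alignment.** With maximum lag `d·m`, the first `d·m` rows are dropped
  from every realization block so all lagged columns share one time
  support; the effective sample size is `N − d·m`.
- **Shuffle test.** The bootstrap threshold draws `B = 100` independent row
  permutations of the winner column and of the target (conditioning block
  untouched), re-estimates the criterion on each, and takes the 95th
  percentile (linear interpolation). For the LA variant the shuffled
  quantity is the full low-dimensional criterion with the shuffled winner
  appearing in the relevance and both redundancy sums.
- **Iteration statistic.** The per-run iteration count is the number of
  *accepted* candidates (the embedding size) summed over the 5 targets; the
  final rejected test is not counted. Under the pure-prediction settings
  (`λ = 1, γ = 0`) this reproduces the published mean counts (16.2 on the
  Hénon ring, ~10.5 on the AR system) while counting the rejected test
  would add exactly one per target.
- **Theiler window.** Default 0 for simulated data; a positive window
  excludes `|i−j| ≤ w` pairs from all neighbor searches (for real recordings
  with slow autocorrelation, downsample and/or set a window of a few
  samples).

## Synthetic data

`simulate_henon` implements the 5-node coupled Hénon ring: free ends
(`y = 1.4 − y² + 0.3 y_{-2}`), interior nodes squaring the coupling-weighted
mixture `0.5Q(left + right) + (1−Q) self`. Initial conditions are i.i.d.
uniform on `[0, 0.5]`; 1000 burn-in samples are discarded; trajectories
escaping `|y| > 10^4` are redrawn (bounded retries). `Q` between 0.2 and
0.8 avoids complete synchronization.

`simulate_ar` implements the 5-node nonlinear AR benchmark (coefficients
`0.95√2`, `−0.9025`, `0.25√2`; unit Gaussian innovations; zeros before
t = 0; 1000 burn-in samples). Node 1 is a stochastic oscillator driving
nodes 2–4, twice through squares, so half the couplings are invisible to
linear measures. Ground truth: `1→2, 1→3, 1→4, 2→3, 4→5`. Note the system
contains near-duplicate nodes — `y4(t−1) ≈ −y2(t)` (correlation ≈ −0.93)
because both are dominated by `0.5·y1²` at adjacent lags — which makes the
uncoupled pair `4→2` genuinely hard to reject for any greedy selector once
the observed channels are degraded.

`mix_instantaneous` post-multiplies the raw simulated record by the
symmetric matrix with `1−α` diagonal and `α` off-diagonal, emulating
zero-lag leakage (volume conduction). Mixing is applied to the raw
channels, before standardization. Because the AR channels have very unequal
variances, `α` understates the effective contamination of the
low-variance channels; this is the regime the detectors are scored in.

What the generators do *not* emulate: measurement noise, nonstationarity,
line artifacts, finite sensor montages, or realistic head-model mixing.
Passing benchmarks here demonstrates correct recovery of known simulated
structure, not performance on real recordings.

## Monte-Carlo harness and problem sizes

Metrics (ACC/TPR/TNR over the 20 ordered node pairs) are computed per
realization and averaged (a pooled-count mode exists). Child seeds derive
from `(master_seed, replication)` only, so conditions are compared on
paired realizations and results are independent of grid traversal order.
For the `msr` variant a `γ` grid is evaluated by recording the `γ = 0`
trace once per realization and re-thresholding it — exact, because the
greedy path does not depend on `γ` — which the tests verify against direct
runs.

Replication scales: the headline mixed-AR accuracies and the iteration
counts run at the protocol's 100 realizations; the AIC variant at 30; the
shuffle-terminated comparisons at reduced counts (bootstrap 20, LA 1),
reflecting their 100-shuffle inner loop — the LA variant additionally keeps
accepting on mixed data (see below), which multiplies its per-realization
cost. Qualitative shape checks (accuracy saturation in record length, TNR
across coupling strengths, TNR monotone in `γ`) use 20–30 realizations.

## Known limitations

- The LA comparison variant reproduces the published behavior on unmixed
  data (aggressive early termination, low TPR) but on instantaneously mixed
  data its pairwise `2/|S|`-weighted redundancy correction cannot remove
  mixture information — conditioning on the mixed target inflates the
  conditional-redundancy term — so it keeps accepting marginal candidates
  and its mixed-data accuracy falls well short of the published figure.
  The implementation follows the printed criterion and shuffle recipe; the
  discrepancy is documented rather than patched.
- Greedy selection is not exhaustive: with near-duplicate predictors (the
  AR system above, or any strongly redundant montage) the first-ranked
  proxy can displace the true parent, and the forced first acceptance then
  fixes a false edge that no `γ` can remove. This caps the mixed-AR
  true-negative rate a few points below the published values at
  `α ≥ 0.2`.
- The AIC variant's leave-one-out stop is sharp: on the mixed AR benchmark
  it rejects spurious candidates slightly more reliably than the published
  reference values suggest, so its accuracy there runs a few points *above*
  the published figure.
- KSG estimators degrade with conditioning dimension; embeddings beyond
  ~8–10 selected variables at `N ≈ 500` should be read as exploratory.
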