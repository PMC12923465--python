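# Methods

## Model

`isingscape` works with the Ising network model on 0/1-coded nodes, the
standard parameterization in network psychometrics: node states
`a ∈ {0,1}^N` (symptom present/absent), per-node thresholds `m_i`
(intrinsic activation tendency), symmetric edge weights `w_ij` with
`w_ii = 0` (pairwise conditional associations), and an inverse
temperature `β > 0` (default 1). The energy of a microstate is

    H(a) = −Σ_{i<j} w_ij a_i a_j − Σ_i m_i a_i ,

microstate probabilities follow the Boltzmann distribution
`P(a) ∝ exp(−β H(a))`, and the full conditional of one node given the
rest is `P(a_i = 1 | a_{−i}) = logistic(β (m_i + Σ_{j≠i} w_ij a_j))`.

The ±1 spin convention is deliberately not supported; conversions
between the two conventions change the meaning of thresholds and are a
common source of silent errors.

A note on sign conventions: in this parameterization a *larger*
threshold `m_i` makes node `i` *more* likely to activate (it enters the
logistic with a positive sign). Some of the surrounding literature uses
"threshold" in the opposite, colloquial sense (a barrier to cross, so
larger = less active). We implement the formula, not the colloquialism,
and the test suite pins the direction by exact enumeration: raising
every `m_i` strictly raises the expected number of active nodes.

## Stability landscape

The macrostate is the number of active nodes `n = Σ_i a_i` — for symptom
networks, the symptom count already used clinically as a severity index.
Its steady-state distribution is obtained exactly by grouping the
enumerated Boltzmann distribution by `n` ("exactly" meaning no
simulation: all `2^N` states are enumerated, with a hard guard at
`N = 25`; empirical symptom networks have `N ≈ 9–20`). The generalized
potential is

    U(n) = −ln P_SS(n) .

Local minima of `U` are the stable phases; lower is more stable. `U` is
defined only up to an additive constant (the normalization of `P_SS`),
and every metric built here is a difference of `U` values, so the
constant cancels; we report `U` for `P_SS` normalized to sum 1. All
grouping is done in log space (group-wise log-sum-exp of `−βH`), so
extreme parameters cannot overflow, and macrostates keep finite `U` even
when their probability is ~e^(−700).

### Numerical choices

- Canonical microstate index: the state vector read as an N-bit integer
  with node 0 as the least-significant bit. Fixes ordering for
  serialization and tests.
- Minima detection uses weak inequalities; a plateau of equal values
  that is flanked by strictly larger values reports both its leftmost
  and rightmost index as candidate minima. The healthy phase resolves
  ties to the leftmost index, the disorder phase to the rightmost
  (mirror symmetry). Ties are measure-zero for generic parameters but
  must be deterministic.
- `+inf` potentials (possible only for clamped degenerate parameters)
  are excluded from minima scans.
- Weight matrices asymmetric beyond 1e−8 are rejected; within tolerance
  they are symmetrized by averaging with a warning. Self-loops are
  rejected rather than silently zeroed.

## Phase-stability metrics

A clinical cutoff `c` (the smallest symptom count that counts as
disordered; e.g. 5 of 9 depression symptoms, or 8 of 11 for an anxiety
scale) splits `0..N` into a healthy portion `0..c−1` and a disorder
portion `c..N`. Healthy-phase stability is
`max(U[i*+1 .. c−1]) − U[i*]` where `i*` is the leftmost local minimum
of the healthy portion (0 if `i*` is the portion's right edge); the
disorder phase is scored mirror-symmetrically from its rightmost local
minimum. The stability difference is healthy minus disorder: positive
means the healthy phase is the more stable one.

Two readings of "the maximum to the right of the minimum" are possible;
we fix the within-portion reading (the reference maximum never crosses
the cutoff) and include the portion edge adjacent to the cutoff in the
max scan. Unlike barrier height — which is also provided, for
comparability with earlier work — these metrics remain defined for
single-well landscapes, where barrier height is meaningless and raises
an error.

## Estimation

Networks are estimated from persons × nodes binary data by nodewise
logistic regression (pseudo-likelihood): node `i` regressed on all
others gives `m_i` as the intercept, and `w_ij` as the average of the
two cross-coefficients (symmetrization by averaging, the usual choice
for unregularized pseudo-likelihood; the rule is recorded in the
estimation metadata). `β` is fixed at 1, the scale on which logistic
coefficients are identified.

The solver is a batched Newton–Raphson: all `N` regressions iterate
jointly on a stacked design tensor. This is mathematically identical to
fitting each regression separately (the test suite checks agreement
with scikit-learn's solver to 1e−4) and exists because resampling
workflows re-fit thousands of small networks; the batched solver keeps a
full bootstrap-with-jackknife run in seconds.

Edge cases: ordinal inputs are binarized as `value ≥ t` (default
`t = 1`, absence vs. any presence); constant columns cannot be regressed
and get thresholds clamped to ±10/β with their weight row zeroed (keeps
landscapes finite; warned); perfect separation in an unpenalized fit
raises an error instructing a nonzero L2 ridge (the ridge applies to
slopes only, never the intercept). Estimation is deterministic and
row-order invariant.

## Inference

The stability difference has a skewed sampling distribution, so
uncertainty uses the bias-corrected and accelerated (BCa) nonparametric
bootstrap: persons resampled with replacement, the network re-estimated
and re-scored per replicate; bias correction `z₀` from the fraction of
replicates below the point estimate (ties counted half); acceleration
`a` from a delete-one-person jackknife. The p-value inverts the
interval: the smallest `α` on a 0.001-step grid at which the `(1−α)`
BCa interval excludes the null value. Replicates whose estimation fails
are dropped and counted; more than 5% failures flags the result invalid.
A collapsed bootstrap distribution (zero SE) yields a degenerate result
with an undefined (NaN) p-value rather than a fake zero.

Group comparison: optional size equalization by seeded subsampling of
the larger group (so power differences do not masquerade as structural
differences), per-group landscapes and metrics, and a between-group
contrast (difference of stability differences) bootstrapped with
stratified within-group resampling — the resampling scheme for the
contrast is our choice, as is the default `B = 1000`. A 2×2
parameter-swap grid (thresholds from one group × weights from the
other; diagonal = the pure groups) attributes an observed contrast to
thresholds versus connectivity. A two-sided permutation test on mean
symptom counts (`p = (1 + #{|T_perm| ≥ |T_obs|}) / (B + 1)`) is provided
as a post hoc severity check.

All randomness flows from one user seed through `SeedSequence`
spawning: subsample, per-group bootstrap, between-group and permutation
streams are derived deterministically, so every result is reproducible
bit-for-bit for a fixed seed within one release.

## Simulation and synthetic data

Glauber dynamics (random-scan single-site updates from the full
conditional; random scan keeps the stationarity argument clean) serves
as the stochastic cross-check of the analytic landscape: detailed
balance makes the Boltzmann distribution stationary, which the tests
verify exactly for tiny `N` by brute-forcing the one-sweep transition
operator averaged over visit orders. Burn-in defaults to 10% of sweeps.

Exact i.i.d. sampling draws canonical state indices categorically from
the enumerated distribution. The synthetic-group generator samples
group A from a base network and group B from a shifted/scaled variant
(`m + shift`, `W × multiplier`) and returns the generating networks as
ground truth.

Default synthetic study conditions, fixed once: random networks with
weights `N(0, 0.3²)` and thresholds `N(0, 0.5²)` (the magnitudes typical
of estimated symptom networks; heavier-tailed variants differ mainly in
how often bistability appears); parameter-recovery truth of 5 nodes with
`|w|, |m| ≲ 1` and 10⁴ exact samples; type-I calibration with two groups
of 400 drawn from one 5-node model (weights `N(0, 0.4²)`, thresholds
`N(−0.3, 0.6²)`), 200 simulation replicates at `B = 200`, scored at
cutoff 1 — for these magnitudes the landscape has a single well around
`n ≈ 2`, and a cutoff below the well is what keeps the statistic
continuous rather than identically zero.

What the generator does *not* emulate: real symptom data are not exact
Ising samples — they carry measurement error, ordinal granularity,
population heterogeneity and missingness. Passing recovery and
calibration tests therefore shows the estimator and the inference
machinery are correct *under the model*, not that the model fits any
particular scale.

## Known limitations

- Exact enumeration is exponential in `N`; above the guard (N = 25)
  only the Glauber route is available, and its mixing time can be long
  for strongly bistable systems (the concentration test deliberately
  uses a single-basin network for this reason).
- Landscapes from cross-sectional group data describe the group, not
  any individual; within-person claims need longitudinal models outside
  this package's scope.
- The sum score `n` treats all symptoms as exchangeable severity units;
  for networks mixing qualitatively different node types the macrostate
  loses meaning.
- BCa p-values are resolved on a 0.001 grid and are B-limited; very
  small p-values should be read as bounds.
- No eLasso/EBIC model selection and no missing-data imputation (rows
  with missing cells are dropped with a count); regularization beyond a
  plain L2 ridge is out of scope.
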