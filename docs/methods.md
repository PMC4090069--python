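# Methods

## The symmetry measure

A weighted directed network of `N` neurons without self-edges is stored as
an `N × N` matrix of non-negative efficacies, `w_ij` = strength of the
connection from presynaptic neuron `j` onto postsynaptic neuron `i` (the
orientation only matters for the simulator; the measure is
transpose-invariant). Each unordered pair maps to
`z = |w_ij − w_ji|/(w_ij + w_ji)` and the measure is `s = 1 − mean(z)` over
the `P = N(N−1)/2 − n₀` pairs with at least one nonzero weight. `(0,0)`
pairs are excluded: mathematically they are 0/0, and practically weights
below detection would otherwise flood the statistic. A configurable
detection floor (default 0, i.e. only exact zeros excluded) lets users
emulate a measurement threshold.

Pairs are iterated unordered (`i < j`). Summing over ordered pairs instead
would double every term and the normalisation alike, leaving `s` unchanged;
the unordered convention is asserted against a brute-force double loop in
the tests.

## Null models

Weights are i.i.d. draws from one of two families on `[w_min, w_max]`
(default `[0, 1]`; `s` is scale invariant so this is a convention):

- **uniform**;
- **truncated Gaussian** with mean at the interval centre and standard
  deviation `sigma` (default 0.1, i.e. variance 0.01, the case-study value).
  The spec of the family requires the truncated mass outside the bounds to
  be below 1e−4, so the truncation is a formality and sums/differences of
  weights remain effectively Gaussian. Sampling is by rejection from the
  parent normal — exact, with a rejection rate below 1e−4 under that
  constraint.

**Pruning** removes each directed connection independently with probability
`p` (permanently: the simulator holds pruned entries at zero). Conditioned
on a pair being counted, the both-alive continuous part has mixture weight
`(1−p)/(1+p)` and the one-alive part (which sits on the line `v = u`, i.e.
`z = 1`) has weight `2p/(1+p)`, giving the exact identity
`E[z^k; p] = [(1−p) E[z^k; 0] + 2p]/(1+p)`.

Unpruned moments: for the uniform family the closed forms
`E[z] = 2 ln 2 − 1` and `E[z²] = 3 − 4 ln 2` (double integrals of
`|a−b|/(a+b)` over the unit square). For the Gaussian family the moments
are computed by adaptive 2-D quadrature of `z` over the two weights'
densities, restricted to the smooth half-domain `b < a` and doubled (the
integrand has a kink on the diagonal; the half-domain keeps the quadrature
fast and accurate to ~1e−10, cross-checked against a 10⁶-pair Monte-Carlo
oracle and the half-normal approximation `E[z] ≈ (2σ/√π)·E[1/u]`). The
factorised `(u, v)` product density is exposed in the density bundle as a
documented cross-check, not as the moment route.

Across networks, `s` is a sample mean of i.i.d. pair variables, so
`μ_s = 1 − μ_z` and `Var[s] = Var[z]/E[P]` with
`E[P] = (1−p²)·N(N−1)/2` (binomial pair survival). The number of counted
pairs varies between realisations; using its expectation in the denominator
is exact for the mean and accurate for the variance at the study sizes
(MC agreement within sampling error at `N = 30`, `M = 10⁴`).

A noteworthy exact fact: for both families `u = a + b` and `v = |a − b|`
are *uncorrelated* (for any i.i.d. symmetric draw,
`E[uv] = E|a² − b²|` equals `E[u]E[v]`; for uniform weights both sides are
1/3). For the Gaussian family this justifies factorising the joint `(u, v)`
density; the measured Pearson correlation at 10⁶ pairs is ~1e−4 for both
families.

## Hypothesis test and motifs

Over random networks `s` is a mean of hundreds of i.i.d. terms, so its null
distribution is taken as Gaussian with the analytic moments; no small-`P`
correction is applied. The test reports `z = (s_obs − μ_s)/σ_s` and a
p-value; the default is **two-sided** (conservative; one-sided variants are
exposed for directional questions such as the protocol experiments).
Rejection with `s_obs > μ_s` is read as "symmetric", below as "asymmetric",
non-rejection as "random".

The null mean also fixes the motif threshold `z̄ = 1 − μ_s`: counted pairs
with `z > z̄` are classified unidirectional, the rest bidirectional (ties
count as bidirectional). Because the two fractions are complementary, their
curves against `s` cross exactly at 0.5, and they do so at the null mean.
Over prescribed-`s` ensembles the mean bidirectional fraction is
`Φ((z̄ − (1−s))/σ_z)` — linear in `s` within roughly `±2σ_z` of the
crossing and saturating outside it, so linearity is a *local* property of
the transition window, not of the full `s ∈ (0, 1)` range (with the default
`σ_z = 0.05` the pooled R² over the full range is ≈ 0.79, while a window
around the crossing exceeds 0.95).

## Ensemble generators

- **random**: i.i.d. family draws off-diagonal, then an independent pruning
  mask.
- **symmetric**: upper triangle drawn, mirrored; pruning applied per
  directed connection *after* mirroring, so pruning can remove one side of
  a reciprocal pair — the mechanism by which mirrored networks appear
  increasingly asymmetric as `p` grows.
- **asymmetric**: per pair, one strong family draw and the other side in
  `[0, eps]`, direction chosen at random; `eps = 0` gives `s = 0` exactly
  (used for bracketing), `eps = 0.01` the near-one-way ensemble used in the
  eigenvalue comparison. Pruning cannot raise `s` here: surviving pairs
  remain one-sided.
- **prescribed-s**: per pair, the *larger* weight is drawn from the family,
  `z` from `Normal(1 − s_target, σ_z)` clipped to `[0, 1]` (default
  `σ_z = 0.05`), and the smaller weight is `a(1−z)/(1+z)`. Drawing the
  larger weight keeps both weights inside the bounds by construction; this
  slightly changes the marginal weight distribution relative to filling one
  triangle from the family, which is immaterial because all downstream uses
  condition on the *measured* `s`. `z` clipped at 1 yields a cleanly
  one-way pair (smaller weight exactly 0).

## Eigenvalue comparator

An eigenvalue counts as complex when `|Im λ| > tol·max(1, spectral radius)`
(default `tol = 1e−9`): relative to the spectral radius for scale
invariance, with an absolute floor because rounding can give symmetric
matrices tiny spurious imaginary parts. The sweep reports mean and SD of
the complex fraction per ensemble and pruning level, optionally alongside
the `s` statistics of the identical networks. The comparison shows the
measure's advantage: at `N = 30` the asymmetric(`eps = 0.01`) and random
ensembles' complex-eigenvalue fractions overlap within one pooled ensemble
SD at every pruning level, while their `s` distributions stay ~30/18/11
pooled SDs apart at `p = 0.2/0.4/0.6`. The two ensembles genuinely converge
as `p → 1` (both `s` means approach 0), so the `s` separation falls to ~5 SD
by `p = 0.8` — still an order of magnitude beyond what the eigenvalue
fraction achieves, but no longer a double-digit gap.

## Spiking-network case study

`N` leaky integrate-and-fire neurons (default 30; the protocol experiments
in the tests use 10), all-to-all plastic excitatory coupling.

- **Membrane**: `τ_m dV/dt = −(V − V_rest) + R·I`, with
  `τ_m = 10 ms`, `R = 1`, `V_rest = V_reset = −70 mV`, threshold reference
  `V_θ = −50 mV`, `dt = 1 ms`. Linear decays (membrane and all traces) use
  exact per-step exponential factors rather than forward Euler:
  unconditionally stable at `dt = 1 ms` and unit-testable in closed form.
  Synaptic impulses deliver `J_syn·w_ij = 1 mV` per unit weight after a
  one-step conduction delay; external events deliver `J_ext = 30 mV`, which
  forces a spike from rest.
- **Escape noise**: per-step firing probability
  `P = 1 − exp(−dt·ρ(V))`, `ρ(V) = ρ₀·exp((V − V_θ)/ΔV)` with defaults
  `ρ₀ = 1/ms`, `ΔV = 2 mV` — deep subthreshold firing below 1e−4 per step,
  near-certain firing after an external kick. After a spike the membrane
  resets to `V_rest`.
- **Triplet STDP**: presynaptic traces `r1, r2` (τ = 16.8 / 575 ms) and
  postsynaptic traces `o1, o2` (τ = 33.7 / 47 ms). When neuron `k` fires,
  incoming weights potentiate by `η·r1_j·(A2⁺ + A3⁺·o2_k⁻)` and outgoing
  weights depress by `η·o1_j·(A2⁻ + A3⁻·r2_k⁻)`, where the `⁻` traces are
  read before the increment caused by that very spike (the step order is:
  decay traces → membrane update → spike draw → STDP → trace set).
  Amplitudes default to the published nearest-spike triplet parameter set
  fitted to visual-cortex data (`A2⁺ = 4.6e−3`, `A3⁺ = 9.1e−3`,
  `A2⁻ = 3.0e−3`, `A3⁻ = 7.5e−9`); consistent with that set, traces reset
  to 1 on a spike by default (the accumulative `+1` variant is a config
  switch). Weights are clipped to `[0, 1]` after every update; entries
  pruned before learning stay zero throughout.
- **Protocols**: *frequency* — each neuron receives periodic external
  events at its own rate, evenly spaced across neurons between 15 and
  30 Hz, jittered with SD = 5% of the period; neurons that fire together at
  sustained rates potentiate both directions of a pair, driving `s` towards
  its (pruning-limited) maximum. *Sequential* — neurons receive events in a
  fixed order with a 20 ms inter-neuron delay (jitter SD = 5% of the
  delay); the fixed temporal order potentiates forward connections and
  depresses reverse ones, driving `s` down. Learning-rate defaults are
  `η = 1.0` (frequency) and `η = 0.5` (sequential), chosen so that the
  drift saturates within a 200-simulated-second window at `N = 10` — the
  problem size used by the protocol tests and the acceptance script
  (10 and 5 seeds per protocol respectively). Both directions of drift hold
  for either initial weight family and for pruning up to at least 0.2.

Initial weights are drawn from the configured family (uniform, or Gaussian
with mean 0.5 and variance 0.01); the distribution of `s` at `t = 0` over
seeds matches the analytic null (KS-tested). Runs are bitwise reproducible
per seed.

## What the generators emulate — and what they do not

The synthetic ensembles realise the statistical assumptions of the null
models exactly: i.i.d. weights, independent Bernoulli pruning, no degree
structure, no inhibition, no weight–distance coupling. Real connectomes
violate most of these (broad lognormal-ish weights, degree correlations,
cluster structure), so a passing test shows the statistic behaves as derived
*under the stated null*, not that any particular biological network is well
described by it. The hypothesis test inherits the usual caveat that its
verdict is only as meaningful as the chosen null family — which is precisely
the point the uniform-vs-Gaussian comparison makes.

## Numerical choices and degenerate inputs

- Quadrature tolerances 1e−10 (absolute/relative), with an error of 1e−8
  triggering a hard failure rather than a silent result.
- An all-zero matrix raises an "undefined measure" error instead of
  returning 0 or 1; a zero-variance null likewise refuses to test.
- `p = 1` pruning is rejected (no counted pairs in expectation).
- Ties at the motif threshold are bidirectional (strict inequality defines
  the unidirectional class).
- Matrix file diagonals below 1e−12 are forced to exact zero on read;
  larger diagonal entries are rejected.

## Known limitations

- The Gaussian-family variance of `s` uses the expected counted-pair count
  in the denominator; at very small `N` combined with heavy pruning the
  fluctuation of `P` itself contributes at second order.
- The normal approximation of the `s` null degrades for very small `P`
  (say, below ~20 counted pairs); no exact small-sample correction is
  provided.
- The simulator is a minimal case study: current-based synapses, no
  inhibition, single fixed conduction delay, and protocol constants chosen
  for a compact demonstration rather than fitted to data.
- Signed (inhibitory) weights, multigraphs and self-edges are out of scope
  by design.
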