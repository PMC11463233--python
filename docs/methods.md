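# Methods

## Model

`n` agents each maintain an estimate `κᵢ` of a target direction, rescaled so
that the truth is 0 and a lone agent's private signal has unit variance. At
every step each agent blends a fresh private signal with the perceived mean
heading of the group:

    κᵢ ← wᵢ zᵢ + (1 − wᵢ)/n · Σⱼ (κⱼ + νᵢⱼ),      zᵢ ~ N(0, εᵢ²),  νᵢⱼ ~ N(0, γᵢ²)

`wᵢ` is the agent's weighting of private over social information, `εᵢ` its
private-signal noise and `γᵢ` its observation noise on each groupmate
(including itself; the sum runs over all `n` agents). The agent's
navigation error is `σᵢ = sd(κᵢ)` and `ρ` denotes the correlation between
two agents' errors.

## Homogeneous equilibrium (`collnav.homogeneous`)

With identical agents (`ε = 1`), squaring the update and taking expectations
gives coupled recursions for `σ²` and `ρ` whose fixed point is

    ρ  = (1 − w)² / (n − (1 − w)²(n − 1))
    σ² = (n w² + (1 − w)² γ²) / (n − (1 − w)²(1 + (n − 1) ρ))

Both are verified in the test suite by iterating the dynamic recursions to
convergence and, independently, by direct stochastic simulation. `w = 0` is
rejected (`DegenerateEquilibriumError`): with no private input the group mean
performs a random walk and no stationary error exists.

- **Collective optimum** `w*`: minimizer of `σ(w)`. Found by a grid scan
  (step `1e-3`) plus bounded scalar refinement; when the minimum lies at the
  lowest grid point the bracket is reopened down to `1e-12`, since `w*` can
  be arbitrarily small at low `γ`.
- **Best response**: a lone deviant playing `w'` against residents at `w`
  minimizes its own error at
  `w' = (σ²(1 + (n−1)ρ) + γ²) / (n + σ²(1 + (n−1)ρ) + γ²)`.
- **ESS**: fixed point of the best-response map, found by damped iteration
  from `w = 1` (damping 0.5 engages on oscillation; tolerance `1e-8`). The
  ESS always weights private information no more than `w*`: an individual
  ignores the positive externality its private signal confers on others.

## Two-type groups (`collnav.mixed`)

`nA` experts (noise `εA = 1`) and `nB` naive agents (noise `ε ≥ 1`). Each
agent splits social attention between the type-A mean (fraction `α`) and the
type-B mean. The equilibrium is a five-variable fixed point
(`σA, σB, ρAA, ρBB, ρAB`) iterated from `σA = 1, σB = ε, ρ = 0`.

Best responses are derived, not transcribed: writing the variance of the
blended social signal as `g(α)`, the focal agent's error is
`w²ε² + (1−w)² g(α)`, minimized at `w' = g/(ε² + g)` and at

    α' = ζB / (ζA + ζB),   ζX = SX/nX − C + γ²/nX

where `SX` is the type-X mean-heading variance and `C` the between-type
covariance. A property test checks `α'` against brute-force minimization on
a 200 001-point grid. Because `ζ` does not involve the focal agent's own
noise, both types share the same attention split exactly (`αA' = αB'`).

The ESS alternates best responses with damping; the collective optimum
minimizes the root-mean-square group error by Nelder–Mead in logit space
(so box constraints are implicit), multi-started from the symmetric point,
the ESS, and three seeded random points.

## Evolution of specialization (`collnav.evolution`)

Per-agent genomes `(w, ε, γ)` with fitness `F = −σ − ε⁻ᵏ − γ⁻ᵏ`: accuracy
plus a cost for precision in either information channel, with cost profile
exponent `k`. The error `σᵢ` is evaluated at the equilibrium of the full
heterogeneous covariance recursion. That recursion closes over a single
scalar, the variance `V` of the group mean:

    V = b / (1 − a),   a = (Σₖ(1 − wₖ)/n)²,
    b = (1/n²) Σₖ (wₖ² εₖ² + (1 − wₖ)² γₖ²/n)

    σᵢ² = wᵢ² εᵢ² + (1 − wᵢ)² (V + γᵢ²/n)

Note the diagonal of the heading covariance must carry both the private-
signal term `wₖ²εₖ²` and the averaged observation noise `(1−wₖ)²γₖ²/n`; a
simpler recursion that adds a bare `γₖ²` on the diagonal is dimensionally
tempting but wrong — it fails against direct simulation (and suppresses
specialization entirely). The implemented form is verified element-wise
against the simulated heading covariance within Monte Carlo error.

Dynamics: agents start at `w ~ U(0,1)`, `ε, γ ~ Exp(1)`. Each step one
random agent trials a mutation (`w' ~ N(w, 0.01²)` clipped to [0,1];
`log ε', log γ' ~ N(log ·, 0.01²)`) and adopts it iff its own fitness
strictly increases, others held fixed. Default run length is `50 000 n`
steps. A run is classified `leader_follower` when `max(w) − min(w) > 0.5`,
else `common_strategy`.

## Stochastic simulator (`collnav.montecarlo`)

Runs the agent update directly for `R` replicate groups in parallel,
discarding a burn-in (default `T/2`). Because post-burn-in samples are
autocorrelated, `σ̂`, `ρ̂` and covariance estimates use pooled
ratio-of-means estimators with delta-method standard errors; per-replicate
ratio averaging is biased at these sample sizes and is deliberately avoided.

## Numerical results and known behavior

- At `n = 2, k = 1`, runs split cleanly into two basins (final `w`-ranges
  all below 0.05 or above 0.95); the divergent leader–follower outcome
  occurs in 67 ± 2 % of runs (402/600 pooled). The outcome label is
  step-converged: on 200 matched seeds the classification is identical at
  20 000, 50 000 and 100 000 steps, so reduced-length runs (20 000 steps)
  are used for replicated experiments.
- Scanning `k` at `n = 2` (grid 0.5–3.0, step 0.25, 10 replicates) places
  the critical exponent at 1.625 (midpoint between the largest
  majority-divergent and smallest majority-common `k`). The precise value
  depends on the arbitrary fitness function and grid resolution.
- At weak information costs (`k ≲ 0.5`) in larger groups, a minority of
  runs lock into multi-leader states: several agents reach `w = 1` with
  runaway `γ`, each effectively navigating alone. These are genuine local
  equilibria of the adaptive dynamics — once `γ` is large, reducing `w` is
  second-order harmful — and they persist at 10× run length. At moderate
  cost (`k = 1`) a single leader emerges reliably, and the leader's `w`
  declines with group size (≈ 1.0 / 0.45 / 0.33 at n = 2 / 5 / 10).

## Limitations

- The analytic layer treats the covariance recursion at its fixed point;
  transient (pre-equilibrium) fitness is not modeled.
- The mutation–selection rule is strict hill-climbing by a single agent per
  step; it admits local equilibria (see multi-leader states above) and has
  no drift, so outcome frequencies depend on the initialization law.
- Headings live on the real line, a small-angle rescaling of a circular
  process; wrap-around effects at large errors are outside the model.
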