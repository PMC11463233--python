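"""Mutation-selection dynamics over per-agent navigation strategies.

Each agent carries its own target weighting ``w``, private-signal noise
``epsilon`` and social-observation noise ``gamma``.  Precision is costly:
fitness is F_i = -sigma_i - epsilon_i^{-k} - gamma_i^{-k}, where sigma_i is
the agent's equilibrium target error in the current group and ``k`` tunes
the cost profile.  One agent at a time trials a small random mutation and
keeps it iff its fitness strictly increases.  Depending on ``k`` the group
either splits into leader (high w, low epsilon, high gamma) and follower
(low w, high epsilon, low gamma) phenotypes or converges on a common
intermediate strategy; `bifurcation_scan` locates the critical ``k``.

The heterogeneous estimate-covariance equilibrium closes over a single
scalar, the variance V of the group-mean estimate, which obeys a linear
recursion V' = a V + b with a = (sum_k (1-w_k)/n)^2.  Its fixed point
b/(1-a) is evaluated in closed form, making each fitness evaluation O(n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .homogeneous import ConvergenceError, DegenerateEquilibriumError

__all__ = [
    "AgentGenome",
    "EvolutionConfig",
    "EvolutionTrace",
    "BifurcationResult",
    "equilibrium_covariance",
    "fitness",
    "propose_mutation",
    "evolve",
    "classify_outcome",
    "bifurcation_scan",
]

#: w-range above which a final population counts as leader/follower split
LEADER_FOLLOWER_W_RANGE = 0.5


@dataclass(frozen=True)
class AgentGenome:
    """Heritable per-agent strategy: target weighting and the two noise scales."""

    w: float
    epsilon: float
    gamma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"w must lie in [0, 1], got {self.w!r}")
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon!r}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma!r}")


@dataclass(frozen=True)
class EvolutionConfig:
    """Settings for one mutation-selection run.

    ``steps`` defaults to 50000 * n mutation trials; ``mutation_sd`` is the
    s.d. of the w-perturbation and of the log-scale epsilon/gamma
    perturbations; ``accept_on`` selects the acceptance criterion: full
    fitness (default) or raw target error only (``"sigma"``).
    """

    n: int
    k: float
    steps: int | None = None
    mutation_sd: float = 0.01
    seed: int | None = None
    thin: int | None = None
    accept_on: str = "fitness"
    classify_threshold: float = LEADER_FOLLOWER_W_RANGE
    record_fitness: bool = False

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not self.k > 0:
            raise ValueError("k must be > 0")
        if self.steps is not None and self.steps < 1:
            raise ValueError("steps must be >= 1")
        if not self.mutation_sd > 0:
            raise ValueError("mutation_sd must be > 0")
        if self.accept_on not in ("fitness", "sigma"):
            raise ValueError("accept_on must be 'fitness' or 'sigma'")

    @property
    def resolved_steps(self) -> int:
        return self.steps if self.steps is not None else 50_000 * self.n

    @property
    def resolved_thin(self) -> int:
        return self.thin if self.thin is not None else max(1, self.resolved_steps // 1000)


@dataclass
class EvolutionTrace:
    """Recorded history of one run: thinned genome snapshots, per-step
    acceptance flags and actors, and the final population."""

    snapshot_steps: np.ndarray          # (S,)
    snapshots: np.ndarray               # (S, n, 3): columns w, epsilon, gamma
    accepted: np.ndarray                # (steps,) bool
    actors: np.ndarray                  # (steps,) int
    final_genomes: list[AgentGenome]
    outcome: str
    seed: int | None
    degenerate_rejections: int = 0
    fitness_before: np.ndarray | None = None
    fitness_after: np.ndarray | None = None
    config: EvolutionConfig | None = field(default=None, repr=False)


def _pool_terms(w, eps, gam, n):
    """Per-agent injected-variance terms b_i and the coupling sum S1."""
    b = [(wi * wi * ei * ei + (1.0 - wi) ** 2 * gi * gi / n) / (n * n)
         for wi, ei, gi in zip(w, eps, gam)]
    S1 = sum(1.0 - wi for wi in w)
    return b, S1


def equilibrium_covariance(genomes: list[AgentGenome]
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Equilibrium covariance matrix of the agents' estimates and per-agent
    target errors sigma_i.

    The update rule couples agents only through the group-mean estimate, so
    the covariance recursion closes over its variance V:
    V = b / (1 - a) with a = (mean(1-w))^2 and
    b = (1/n^2) sum_i (w_i^2 eps_i^2 + (1-w_i)^2 gamma_i^2 / n).
    Then cov[i,j] = (1-w_i)(1-w_j) V for i != j and
    sigma_i^2 = w_i^2 eps_i^2 + (1-w_i)^2 (V + gamma_i^2 / n).
    """
    n = len(genomes)
    if n < 2:
        raise ValueError("need at least 2 agents")
    w = np.array([g.w for g in genomes])
    eps = np.array([g.epsilon for g in genomes])
    gam = np.array([g.gamma for g in genomes])
    b_terms, S1 = _pool_terms(w, eps, gam, n)
    a = (S1 / n) ** 2
    b = float(sum(b_terms))
    if a >= 1.0:
        if b == 0.0:
            V = 0.0
        else:
            raise DegenerateEquilibriumError(
                "all target weightings are zero: no finite equilibrium"
            )
    else:
        V = b / (1.0 - a)
    inj = w**2 * eps**2 + (1.0 - w) ** 2 * gam**2 / n
    cov = np.outer(1.0 - w, 1.0 - w) * V
    np.fill_diagonal(cov, inj + (1.0 - w) ** 2 * V)
    sigma = np.sqrt(np.diag(cov))
    return cov, sigma


def fitness(agent_index: int, genomes: list[AgentGenome], k: float) -> float:
    """F_i = -sigma_i - epsilon_i^{-k} - gamma_i^{-k}: accuracy rewarded,
    precision of either information channel penalized."""
    _, sigma = equilibrium_covariance(genomes)
    g = genomes[agent_index]
    return float(-sigma[agent_index] - g.epsilon ** (-k) - g.gamma ** (-k))


def propose_mutation(genome: AgentGenome, rng: np.random.Generator,
                     mutation_sd: float = 0.01) -> AgentGenome:
    """Local mutation: w perturbed additively (clipped to [0, 1]); epsilon and
    gamma perturbed multiplicatively on the log scale."""
    w = float(np.clip(genome.w + mutation_sd * rng.standard_normal(), 0.0, 1.0))
    eps = float(genome.epsilon * math.exp(mutation_sd * rng.standard_normal()))
    gam = float(genome.gamma * math.exp(mutation_sd * rng.standard_normal()))
    return AgentGenome(w=w, epsilon=eps, gamma=gam)


def classify_outcome(final_genomes: list[AgentGenome],
                     threshold: float = LEADER_FOLLOWER_W_RANGE) -> str:
    """Label a final population: ``leader_follower`` if the spread of target
    weightings exceeds ``threshold`` (one agent attends to the environment,
    the rest follow), else ``common_strategy``."""
    ws = [g.w for g in final_genomes]
    return "leader_follower" if max(ws) - min(ws) > threshold else "common_strategy"


def evolve(config: EvolutionConfig) -> EvolutionTrace:
    """Run the mutation-selection dynamics.

    Initial genomes: w ~ U(0,1), epsilon ~ Exp(1), gamma ~ Exp(1) per agent.
    Each step one uniformly chosen agent trials a mutation, adopted iff its
    fitness strictly increases with all other agents held fixed.  Proposals
    that would destroy the finite equilibrium (all w -> 0) are rejected and
    counted.  Fully reproducible from ``config.seed``.
    """
    n = config.n
    k = config.k
    steps = config.resolved_steps
    thin = config.resolved_thin
    sd = config.mutation_sd
    sigma_only = config.accept_on == "sigma"
    rng = np.random.default_rng(config.seed)

    w = rng.uniform(0.0, 1.0, n).tolist()
    eps = rng.exponential(1.0, n).tolist()
    gam = rng.exponential(1.0, n).tolist()

    b, S1 = _pool_terms(w, eps, gam, n)
    B = sum(b)

    n_snap = steps // thin + 1
    snapshot_steps = np.empty(n_snap, dtype=np.int64)
    snapshots = np.empty((n_snap, n, 3))
    accepted = np.zeros(steps, dtype=bool)
    actors = np.empty(steps, dtype=np.int32)
    fit_before = np.empty(steps) if config.record_fitness else None
    fit_after = np.empty(steps) if config.record_fitness else None

    def take_snapshot(si: int, step: int) -> None:
        snapshot_steps[si] = step
        snapshots[si, :, 0] = w
        snapshots[si, :, 1] = eps
        snapshots[si, :, 2] = gam

    take_snapshot(0, 0)
    si = 1
    degenerate = 0
    n2 = n * n
    inv_n = 1.0 / n

    chunk = 8192
    done = 0
    while done < steps:
        m = min(chunk, steps - done)
        idx = rng.integers(0, n, m).tolist()
        dz = (sd * rng.standard_normal((m, 3))).tolist()
        for s in range(m):
            step = done + s
            i = idx[s]
            actors[step] = i
            wi, ei, gi = w[i], eps[i], gam[i]
            dw, de, dg = dz[s]
            w_new = wi + dw
            if w_new < 0.0:
                w_new = 0.0
            elif w_new > 1.0:
                w_new = 1.0
            e_new = ei * math.exp(de)
            g_new = gi * math.exp(dg)

            a_old = (S1 * inv_n) ** 2
            V_old = B / (1.0 - a_old)
            sig_old = math.sqrt(
                wi * wi * ei * ei + (1.0 - wi) ** 2 * (V_old + gi * gi * inv_n))

            b_new = (w_new * w_new * e_new * e_new
                     + (1.0 - w_new) ** 2 * g_new * g_new * inv_n) / n2
            S1_new = S1 - (1.0 - wi) + (1.0 - w_new)
            a_new = (S1_new * inv_n) ** 2
            if a_new >= 1.0:
                degenerate += 1
                if fit_before is not None:
                    fit_before[step] = fit_after[step] = math.nan
                if (step + 1) % thin == 0:
                    take_snapshot(si, step + 1)
                    si += 1
                continue
            B_new = B - b[i] + b_new
            V_new = B_new / (1.0 - a_new)
            sig_new = math.sqrt(
                w_new * w_new * e_new * e_new
                + (1.0 - w_new) ** 2 * (V_new + g_new * g_new * inv_n))

            if sigma_only:
                F_old, F_new = -sig_old, -sig_new
            else:
                F_old = -sig_old - ei ** (-k) - gi ** (-k)
                F_new = -sig_new - e_new ** (-k) - g_new ** (-k)
            if fit_before is not None:
                fit_before[step] = F_old
                fit_after[step] = F_new

            if F_new > F_old:
                accepted[step] = True
                w[i], eps[i], gam[i] = w_new, e_new, g_new
                S1, B, b[i] = S1_new, B_new, b_new

            if (step + 1) % thin == 0:
                take_snapshot(si, step + 1)
                si += 1
        done += m
        # refresh running sums to cancel float drift
        b, S1 = _pool_terms(w, eps, gam, n)
        B = sum(b)

    final = [AgentGenome(w=w[i], epsilon=eps[i], gamma=gam[i]) for i in range(n)]
    return EvolutionTrace(
        snapshot_steps=snapshot_steps[:si],
        snapshots=snapshots[:si],
        accepted=accepted,
        actors=actors,
        final_genomes=final,
        outcome=classify_outcome(final, config.classify_threshold),
        seed=config.seed,
        degenerate_rejections=degenerate,
        fitness_before=fit_before,
        fitness_after=fit_after,
        config=config,
    )


@dataclass
class BifurcationResult:
    """Outcome table of a scan over the information-cost exponent."""

    rows: list[dict]          # k, replicate, agent, final_w/epsilon/gamma, outcome
    outcomes: dict[float, list[str]]
    critical_k: float | None
    failures: list[tuple[float, int, str]]


def bifurcation_scan(k_grid, config_template: EvolutionConfig,
                     replicates: int) -> BifurcationResult:
    """Run ``replicates`` independent evolutions at each k and estimate the
    critical cost exponent separating leader/follower divergence from
    convergence on a common strategy.

    The estimate is the midpoint between the largest k whose replicate
    majority diverges and the smallest larger k whose majority is common.
    Per-run seeds derive deterministically from the template seed.
    """
    base = config_template.seed if config_template.seed is not None else 0
    rows: list[dict] = []
    outcomes: dict[float, list[str]] = {}
    failures: list[tuple[float, int, str]] = []
    for ki, k in enumerate(k_grid):
        outcomes[float(k)] = []
        for rep in range(replicates):
            seed = int(np.random.SeedSequence([base, ki, rep]).generate_state(1)[0] % (2**31))
            cfg = EvolutionConfig(
                n=config_template.n, k=float(k), steps=config_template.steps,
                mutation_sd=config_template.mutation_sd, seed=seed,
                thin=config_template.thin, accept_on=config_template.accept_on,
                classify_threshold=config_template.classify_threshold,
            )
            try:
                trace = evolve(cfg)
            except (ConvergenceError, DegenerateEquilibriumError) as exc:
                failures.append((float(k), rep, str(exc)))
                continue
            outcomes[float(k)].append(trace.outcome)
            for ai, g in enumerate(trace.final_genomes):
                rows.append({
                    "k": float(k), "replicate": rep, "agent": ai,
                    "final_w": g.w, "final_epsilon": g.epsilon,
                    "final_gamma": g.gamma, "outcome": trace.outcome,
                })
    critical = _estimate_critical_k(outcomes)
    return BifurcationResult(rows=rows, outcomes=outcomes,
                             critical_k=critical, failures=failures)


def _estimate_critical_k(outcomes: dict[float, list[str]]) -> float | None:
    ks = sorted(outcomes)
    div_majority = [k for k in ks if outcomes[k]
                    and sum(o == "leader_follower" for o in outcomes[k])
                    > len(outcomes[k]) / 2]
    if not div_majority:
        return None
    k_div = max(div_majority)
    common_above = [k for k in ks if k > k_div and outcomes[k]
                    and sum(o == "common_strategy" for o in outcomes[k])
                    > len(outcomes[k]) / 2]
    if not common_above:
        return None
    return 0.5 * (k_div + min(common_above))
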