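"""Two-type (expert / naive) groups: equilibrium, collective optimum and ESS.

Type A ("expert") agents receive private signals with unit variance; type B
("naive") agents receive signals with variance epsilon^2 >= 1.  Every agent
observes every other with uniform noise s.d. gamma, and weights its private
signal (w) against a social average in which type-A estimates get relative
weight alpha.  The five equilibrium quantities (sigmaA, sigmaB, rhoAA,
rhoBB, rhoAB) solve a coupled system obtained from the linear update rule;
we iterate it from the purely-environmental initial state (sigmaA=1,
sigmaB=epsilon, all correlations zero) until convergence.

The collectively optimal strategy minimizes the root-mean-square target
error over the four strategy parameters (Nelder-Mead in logit space,
multi-start).  The ESS is the fixed point of the closed-form best-response
map derived from the stationarity of a focal deviant's error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .homogeneous import (
    ConvergenceError,
    DegenerateEquilibriumError,
    FIXED_POINT_TOL,
    MAX_ITER,
)

__all__ = [
    "MixedParams",
    "MixedEquilibrium",
    "mixed_equilibrium",
    "collective_error",
    "collective_optimum",
    "mixed_best_response",
    "mixed_ess",
]


@dataclass(frozen=True)
class MixedParams:
    """Structure and strategy of a two-type group.

    nA, nB are the counts of expert and naive agents; epsilon is the naive
    type's signal noise s.d. (experts are fixed at 1); gamma the uniform
    social-observation noise s.d.; wA, wB the target weightings and
    alphaA, alphaB the relative attention each type pays to expert agents.
    """

    nA: int
    nB: int
    epsilon: float
    gamma: float
    wA: float
    wB: float
    alphaA: float
    alphaB: float

    def __post_init__(self) -> None:
        if self.nA < 1 or self.nB < 1:
            raise ValueError("nA and nB must each be >= 1")
        if self.epsilon < 1.0:
            raise ValueError("epsilon must be >= 1 (naive agents are noisier)")
        if self.gamma < 0.0:
            raise ValueError("gamma must be >= 0")
        for name in ("wA", "wB", "alphaA", "alphaB"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.wA == 0.0 and self.wB == 0.0 and self.gamma > 0.0:
            raise DegenerateEquilibriumError(
                "wA = wB = 0 with gamma > 0 has no finite equilibrium"
            )


@dataclass(frozen=True)
class MixedEquilibrium:
    """Equilibrium target errors by type and the three estimate correlations."""

    sigmaA: float
    sigmaB: float
    rhoAA: float
    rhoBB: float
    rhoAB: float


def _social_variance(p: MixedParams, eq_vals: tuple[float, float, float, float, float],
                     alpha: float) -> float:
    """Variance of the noisy social average followed with attention split ``alpha``.

    SA/SB are the per-type 'effective pooled variances'
    sigma^2 (1 + (n-1) rho); C the cross-covariance sigmaA sigmaB rhoAB.
    """
    sA, sB, rAA, rBB, rAB = eq_vals
    SA = sA * sA * (1.0 + (p.nA - 1) * rAA)
    SB = sB * sB * (1.0 + (p.nB - 1) * rBB)
    C = sA * sB * rAB
    g2 = p.gamma * p.gamma
    a, b = alpha, 1.0 - alpha
    return (
        a * a / p.nA * SA
        + b * b / p.nB * SB
        + 2.0 * a * b * C
        + (a * a / p.nA + b * b / p.nB) * g2
    )


def _social_cov(p: MixedParams, eq_vals, alphaX: float, alphaY: float) -> float:
    """Covariance of the (noise-free) social averages followed by two distinct
    observers with attention splits alphaX, alphaY."""
    sA, sB, rAA, rBB, rAB = eq_vals
    SA = sA * sA * (1.0 + (p.nA - 1) * rAA)
    SB = sB * sB * (1.0 + (p.nB - 1) * rBB)
    C = sA * sB * rAB
    return (
        alphaX * alphaY / p.nA * SA
        + (1.0 - alphaX) * (1.0 - alphaY) / p.nB * SB
        + (alphaX * (1.0 - alphaY) + alphaY * (1.0 - alphaX)) * C
    )


def mixed_equilibrium(params: MixedParams, tol: float = FIXED_POINT_TOL,
                      max_iter: int = MAX_ITER) -> MixedEquilibrium:
    """Solve the coupled five-variable equilibrium system by iteration.

    Starts from sigmaA = 1, sigmaB = epsilon and zero correlations (agents
    initially oriented by private signals alone) and applies the update
    equations until the state changes by less than ``tol`` in every variable.
    """
    p = params
    sA, sB = 1.0, p.epsilon
    rAA = rBB = rAB = 0.0
    for _ in range(max_iter):
        eq_vals = (sA, sB, rAA, rBB, rAB)
        qA = (1.0 - p.wA) ** 2
        qB = (1.0 - p.wB) ** 2
        sA2_new = p.wA**2 + qA * _social_variance(p, eq_vals, p.alphaA)
        sB2_new = (p.epsilon * p.wB) ** 2 + qB * _social_variance(p, eq_vals, p.alphaB)
        sA_new = np.sqrt(sA2_new)
        sB_new = np.sqrt(sB2_new)
        # correlations use the updated variances in the denominator, mirroring
        # the homogeneous dynamic recursion
        rAA_new = qA * _social_cov(p, eq_vals, p.alphaA, p.alphaA) / sA2_new if p.nA > 1 else 0.0
        rBB_new = qB * _social_cov(p, eq_vals, p.alphaB, p.alphaB) / sB2_new if p.nB > 1 else 0.0
        rAB_new = (
            (1.0 - p.wA) * (1.0 - p.wB)
            * _social_cov(p, eq_vals, p.alphaA, p.alphaB)
            / (sA_new * sB_new)
        )
        delta = max(
            abs(sA_new - sA), abs(sB_new - sB),
            abs(rAA_new - rAA), abs(rBB_new - rBB), abs(rAB_new - rAB),
        )
        sA, sB, rAA, rBB, rAB = sA_new, sB_new, rAA_new, rBB_new, rAB_new
        if not np.isfinite(sA) or not np.isfinite(sB):
            raise DegenerateEquilibriumError(
                f"equilibrium iteration diverged for {p!r}"
            )
        if delta <= tol:
            return MixedEquilibrium(float(sA), float(sB), float(rAA), float(rBB), float(rAB))
    raise ConvergenceError(
        f"mixed equilibrium did not converge in {max_iter} iterations; "
        f"last residual state sigmaA={sA}, sigmaB={sB}"
    )


def collective_error(eq: MixedEquilibrium, nA: int, nB: int) -> float:
    """Root-mean-square target error over all agents:
    sqrt((nA sigmaA^2 + nB sigmaB^2) / (nA + nB))."""
    return float(np.sqrt((nA * eq.sigmaA**2 + nB * eq.sigmaB**2) / (nA + nB)))


def mixed_best_response(params: MixedParams, eq: MixedEquilibrium
                        ) -> tuple[float, float, float, float]:
    """Closed-form best responses (wA', wB', alphaA', alphaB') of focal
    deviants against a population at equilibrium ``eq``.

    Both types face the same social-information landscape, so the optimal
    attention split is identical: alpha' = zetaB / (zetaA + zetaB) with
    zetaA = SA/nA - C + gamma^2/nA and zetaB = SB/nB - C + gamma^2/nB.
    The optimal target weighting then balances the private-signal variance
    against psi, the social variance at alpha': wA' = psi/(1+psi),
    wB' = psi/(epsilon^2 + psi).
    """
    p = params
    eq_vals = (eq.sigmaA, eq.sigmaB, eq.rhoAA, eq.rhoBB, eq.rhoAB)
    SA = eq.sigmaA**2 * (1.0 + (p.nA - 1) * eq.rhoAA)
    SB = eq.sigmaB**2 * (1.0 + (p.nB - 1) * eq.rhoBB)
    C = eq.sigmaA * eq.sigmaB * eq.rhoAB
    g2 = p.gamma * p.gamma
    zetaA = SA / p.nA - C + g2 / p.nA
    zetaB = SB / p.nB - C + g2 / p.nB
    if zetaA + zetaB == 0.0:
        raise ZeroDivisionError("zetaA + zetaB = 0: attention split undefined")
    alpha = zetaB / (zetaA + zetaB)
    psi = _social_variance(p, eq_vals, alpha)
    wA = psi / (1.0 + psi)
    wB = psi / (p.epsilon**2 + psi)
    return float(wA), float(wB), float(alpha), float(alpha)


def mixed_ess(nA: int, nB: int, epsilon: float, gamma: float,
              tol: float = FIXED_POINT_TOL, max_iter: int = MAX_ITER
              ) -> tuple[MixedParams, MixedEquilibrium]:
    """ESS strategy: fixed point of equilibrium-solve / best-response
    alternation, started from wA = wB = 1, alphaA = alphaB = 1/2.

    The correlation/error equilibrium is fully re-solved after every
    parameter update so that best responses always see equilibrium values.
    Damping (0.5) kicks in if the parameter updates oscillate.
    """
    p = MixedParams(nA=nA, nB=nB, epsilon=epsilon, gamma=gamma,
                    wA=1.0, wB=1.0, alphaA=0.5, alphaB=0.5)
    prev_step = np.zeros(4)
    damp = 1.0
    for it in range(max_iter):
        eq = mixed_equilibrium(p)
        wA, wB, aA, aB = mixed_best_response(p, eq)
        cur = np.array([p.wA, p.wB, p.alphaA, p.alphaB])
        tgt = np.array([wA, wB, aA, aB])
        step = tgt - cur
        if np.any(step * prev_step < 0):
            damp = 0.5
        new = cur + damp * step
        prev_step = step
        p = replace(p, wA=float(new[0]), wB=float(new[1]),
                    alphaA=float(new[2]), alphaB=float(new[3]))
        if np.max(np.abs(step)) <= tol:
            return p, mixed_equilibrium(p)
    raise ConvergenceError(
        f"mixed ESS iteration did not converge in {max_iter} iterations "
        f"(nA={nA}, nB={nB}, epsilon={epsilon}, gamma={gamma}); "
        f"last strategy {p!r}"
    )


def _objective(x: np.ndarray, nA: int, nB: int, epsilon: float, gamma: float) -> float:
    wA, wB, aA, aB = expit(x)
    try:
        p = MixedParams(nA=nA, nB=nB, epsilon=epsilon, gamma=gamma,
                        wA=wA, wB=wB, alphaA=aA, alphaB=aB)
        eq = mixed_equilibrium(p)
    except (ValueError, ConvergenceError):
        return np.inf
    return collective_error(eq, nA, nB)


def collective_optimum(nA: int, nB: int, epsilon: float, gamma: float,
                       n_random_starts: int = 3, seed: int = 0
                       ) -> tuple[MixedParams, MixedEquilibrium]:
    """Strategy minimizing the collective (RMS) target error.

    Nelder-Mead over logit-transformed parameters keeps all four in (0, 1)
    without explicit bounds.  Multi-start: the symmetric point, the ESS, and
    seeded random points; the best converged restart wins.
    """
    starts = [np.zeros(4)]  # logit(0.5) everywhere
    try:
        p_ess, _ = mixed_ess(nA, nB, epsilon, gamma)
        starts.append(logit(np.clip(
            [p_ess.wA, p_ess.wB, p_ess.alphaA, p_ess.alphaB], 1e-9, 1 - 1e-9)))
    except ConvergenceError:
        pass
    rng = np.random.default_rng(seed)
    for _ in range(n_random_starts):
        starts.append(logit(rng.uniform(0.05, 0.95, size=4)))

    best = None
    for x0 in starts:
        res = minimize(_objective, x0, args=(nA, nB, epsilon, gamma),
                       method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-12, "maxiter": 5000})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise ConvergenceError("all collective-optimum restarts failed")
    wA, wB, aA, aB = expit(best.x)
    p = MixedParams(nA=nA, nB=nB, epsilon=epsilon, gamma=gamma,
                    wA=float(wA), wB=float(wB), alphaA=float(aA), alphaB=float(aB))
    return p, mixed_equilibrium(p)
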