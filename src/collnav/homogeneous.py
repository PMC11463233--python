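"""Equilibrium accuracy and rational strategies for homogeneous navigating groups.

A group of ``n`` identical agents repeatedly estimates the position of a
distant target on the real line.  At each step an agent blends a fresh
private environmental signal (unit variance, unbiased) with the imperfectly
observed current estimates of all group members (observation noise s.d.
``gamma``), giving weight ``w`` to the private signal.  At equilibrium the
standard deviation ``sigma`` of an agent's estimate about the true target
("target error") and the correlation ``rho`` between two agents' estimates
satisfy closed-form relations in (w, n, gamma); this module evaluates them,
finds the collectively optimal weighting ``w*`` that minimizes ``sigma``,
and the evolutionarily stable weighting at which no single agent can reduce
its own error by deviating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "HomogeneousParams",
    "EquilibriumState",
    "ESSResult",
    "DegenerateEquilibriumError",
    "ConvergenceError",
    "equilibrium_rho",
    "equilibrium_sigma",
    "collective_optimal_w",
    "best_response_w",
    "ess_w",
]

#: absolute convergence tolerance for all fixed-point iterations
FIXED_POINT_TOL = 1e-8
#: iteration cap for fixed-point solvers
MAX_ITER = 10_000
#: grid step for the coarse scan preceding scalar polish in w-optimization
W_GRID_STEP = 1e-3


class DegenerateEquilibriumError(ValueError):
    """No finite equilibrium exists for the requested parameters (e.g. w = 0)."""


class ConvergenceError(RuntimeError):
    """An iterative solver failed to reach its tolerance within the iteration cap."""


def _validate(w: float, n: int, gamma: float, *, allow_w0: bool = False) -> None:
    if not (isinstance(n, (int, np.integer)) and n >= 2):
        raise ValueError(f"group size n must be an integer >= 2, got {n!r}")
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"target weighting w must lie in [0, 1], got {w!r}")
    if gamma < 0.0:
        raise ValueError(f"interaction noise gamma must be >= 0, got {gamma!r}")
    if w == 0.0 and not allow_w0:
        raise DegenerateEquilibriumError(
            "w = 0 gives a degenerate equilibrium (perfectly correlated estimates, "
            "no finite target error for gamma > 0)"
        )


@dataclass(frozen=True)
class HomogeneousParams:
    """Strategy and noise regime of a uniform group.

    Attributes
    ----------
    n : int
        Group size (>= 2).
    gamma : float
        Standard deviation of the error with which agents observe each
        other's estimates, on the scale of the unit-variance private signal.
    w : float
        Weight in [0, 1] given to the private environmental signal.
    """

    n: int
    gamma: float
    w: float

    def __post_init__(self) -> None:
        _validate(self.w, self.n, self.gamma, allow_w0=True)


@dataclass(frozen=True)
class EquilibriumState:
    """Equilibrium target error and inter-agent estimate correlation."""

    sigma: float
    rho: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma!r}")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [-1, 1], got {self.rho!r}")


@dataclass(frozen=True)
class ESSResult:
    """Fixed point of the best-response map, with solver diagnostics."""

    w: float
    state: EquilibriumState
    iterations: int


def equilibrium_rho(w: float, n: int) -> float:
    """Equilibrium correlation between two distinct agents' estimates.

    rho = (1-w)^2 / (n - (1-w)^2 (n-1)), which lies in [0, 1) for w in (0, 1].
    """
    _validate(w, n, 0.0)
    q = (1.0 - w) ** 2
    return q / (n - q * (n - 1))


def equilibrium_sigma(params: HomogeneousParams) -> EquilibriumState:
    """Equilibrium target error of a uniform group.

    sigma^2 = (n w^2 + (1-w)^2 gamma^2) / (n - (1-w)^2 (1 + (n-1) rho)).
    """
    n, gamma, w = params.n, params.gamma, params.w
    _validate(w, n, gamma)
    rho = equilibrium_rho(w, n)
    q = (1.0 - w) ** 2
    denom = n - q * (1.0 + (n - 1) * rho)
    sigma2 = (n * w * w + q * gamma * gamma) / denom
    return EquilibriumState(sigma=float(np.sqrt(sigma2)), rho=rho)


def _sigma_of_w(w: float, n: int, gamma: float) -> float:
    return equilibrium_sigma(HomogeneousParams(n=n, gamma=gamma, w=w)).sigma


def collective_optimal_w(n: int, gamma: float) -> tuple[float, EquilibriumState]:
    """Target weighting minimizing the equilibrium error shared by all agents.

    The error curve sigma(w) is smooth with a unique interior minimum, so a
    coarse grid scan brackets the minimum and a bounded scalar minimizer
    polishes it to ~1e-8 in w.
    """
    _validate(1.0, n, gamma)  # validates n, gamma only
    grid = np.arange(W_GRID_STEP, 1.0 + 0.5 * W_GRID_STEP, W_GRID_STEP)
    sig = np.array([_sigma_of_w(w, n, gamma) for w in grid])
    i = int(np.argmin(sig))
    # when the coarse minimum sits on the first grid point the true minimum
    # may lie below the grid step (gamma -> 0 regime): open the bracket there
    lo = grid[i - 1] if i > 0 else 1e-12
    hi = grid[min(i + 1, len(grid) - 1)]
    if lo >= hi:
        raise ConvergenceError("degenerate bracket in w* search")
    res = minimize_scalar(
        _sigma_of_w,
        bounds=(lo, hi),
        args=(n, gamma),
        method="bounded",
        options={"xatol": 1e-9},
    )
    if not res.success:
        raise ConvergenceError(f"w* polish failed: {res.message}")
    w_star = float(np.clip(res.x, 1e-12, 1.0))
    # keep the better of grid point and polish (guards boundary rounding)
    if sig[i] < res.fun:
        w_star = float(grid[i])
    return w_star, equilibrium_sigma(HomogeneousParams(n=n, gamma=gamma, w=w_star))


def deviant_sigma2(w_prime: float, state: EquilibriumState, n: int, gamma: float) -> float:
    """Squared target error of a lone deviant using ``w_prime`` against a
    population at equilibrium ``state``.

    sigma'^2 = w'^2 + (1-w')^2/n * (sigma^2 (1 + (n-1) rho) + gamma^2).
    """
    s = state.sigma**2 * (1.0 + (n - 1) * state.rho)
    return w_prime**2 + (1.0 - w_prime) ** 2 * (s + gamma * gamma) / n


def best_response_w(w_pop: float, n: int, gamma: float) -> float:
    """Weighting minimizing a focal agent's error when the rest of the group
    plays ``w_pop``.

    w' = (sigma^2 (1+(n-1) rho) + gamma^2) / (n + sigma^2 (1+(n-1) rho) + gamma^2).
    """
    state = equilibrium_sigma(HomogeneousParams(n=n, gamma=gamma, w=w_pop))
    s = state.sigma**2 * (1.0 + (n - 1) * state.rho)
    return (s + gamma * gamma) / (n + s + gamma * gamma)


def ess_w(n: int, gamma: float) -> ESSResult:
    """Evolutionarily stable target weighting: the fixed point of the
    best-response map, found by damped iteration from w = 1.

    Damping (factor 0.5) is applied once successive updates start
    oscillating in sign; convergence is |w' - w| <= 1e-8.
    """
    if gamma <= 0:
        raise ValueError("ess_w requires gamma > 0")
    w = 1.0
    prev_step = 0.0
    damp = 1.0
    for it in range(1, MAX_ITER + 1):
        w_next = best_response_w(w, n, gamma)
        step = w_next - w
        if step * prev_step < 0:
            damp = 0.5
        w_new = w + damp * step
        prev_step = step
        if abs(w_next - w) <= FIXED_POINT_TOL:
            state = equilibrium_sigma(HomogeneousParams(n=n, gamma=gamma, w=w_next))
            return ESSResult(w=w_next, state=state, iterations=it)
        w = w_new
    raise ConvergenceError(
        f"ESS iteration did not converge in {MAX_ITER} iterations "
        f"(n={n}, gamma={gamma}, last w={w})"
    )
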