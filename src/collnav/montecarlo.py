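"""Direct stochastic simulation of the heading-update dynamics.

Serves as the independent numerical oracle for every analytic equilibrium
in the package: groups of agents repeatedly blend fresh private signals
with noisy observations of each other's current estimates, and the
empirical spread and correlation of the estimates after a burn-in are
compared with the closed-form equilibria.

All simulations are vectorized over ``R`` independent replicate groups and
are bit-reproducible from the seed.  Initial estimates are drawn as pure
environmental estimates, kappa_0 ~ N(0, epsilon_i^2), matching the
initialization used by the analytic equilibrium solvers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evolution import AgentGenome
from .homogeneous import HomogeneousParams
from .mixed import MixedParams

__all__ = [
    "SimConfig",
    "SimSummary",
    "MixedSimSummary",
    "simulate_homogeneous",
    "simulate_heterogeneous",
    "simulate_mixed",
]


@dataclass(frozen=True)
class SimConfig:
    """Replication layout of a simulation: T time steps, R replicates, seed,
    and the number of initial steps discarded before equilibrium summaries
    (default T // 2)."""

    T: int
    R: int
    seed: int | None = None
    burn_in: int | None = None

    def __post_init__(self) -> None:
        if self.T < 1 or self.R < 1:
            raise ValueError("T and R must be >= 1")
        bi = self.resolved_burn_in
        if not 0 <= bi < self.T:
            raise ValueError("burn_in must satisfy 0 <= burn_in < T")

    @property
    def resolved_burn_in(self) -> int:
        return self.burn_in if self.burn_in is not None else self.T // 2


@dataclass
class SimSummary:
    """Per-step and equilibrium summaries of a simulated ensemble.

    sigma_t / rho_t are trajectories of the empirical estimate s.d. about
    the true target and the mean inter-agent correlation (length T + 1,
    including the initial state).  The *_hat values are post-burn-in
    equilibrium estimates with standard errors from the spread across
    independent replicates.  For heterogeneous groups, per-agent statistics
    and the empirical estimate-covariance matrix are filled in.
    """

    sigma_t: np.ndarray
    rho_t: np.ndarray
    sigma_hat: float
    sigma_se: float
    rho_hat: float
    rho_se: float
    sigma_agent: np.ndarray | None = None
    cov_hat: np.ndarray | None = None
    cov_se: np.ndarray | None = None
    grand_mean: float = 0.0
    grand_mean_se: float = 0.0


@dataclass
class MixedSimSummary:
    """Equilibrium summaries of a simulated two-type ensemble."""

    sigmaA_t: np.ndarray
    sigmaB_t: np.ndarray
    sigmaA_hat: float
    sigmaA_se: float
    sigmaB_hat: float
    sigmaB_se: float
    rhoAA_hat: float
    rhoBB_hat: float
    rhoAB_hat: float
    rhoAB_se: float


def _ratio_stats(num_r: np.ndarray, den_r: np.ndarray) -> tuple[float, float]:
    """Pooled ratio-of-means estimator with a delta-method standard error.

    Using mean(num)/mean(den) over replicates avoids the O(1/T_eff) bias of
    per-replicate ratios when within-replicate samples are autocorrelated.
    """
    R = len(num_r)
    mx, md = np.mean(num_r), np.mean(den_r)
    ratio = mx / md
    vx = np.var(num_r, ddof=1) / R
    vd = np.var(den_r, ddof=1) / R
    cxd = np.cov(num_r, den_r, ddof=1)[0, 1] / R
    var = (vx - 2.0 * ratio * cxd + ratio * ratio * vd) / (md * md)
    return float(ratio), float(np.sqrt(max(var, 0.0)))


def simulate_homogeneous(params: HomogeneousParams, T: int, R: int,
                         seed: int | None = None,
                         burn_in: int | None = None) -> SimSummary:
    """Simulate R independent uniform groups for T steps.

    Each step every agent's estimate becomes w * z + (1-w) * (group mean +
    observation noise), with z ~ N(0,1) and the per-observer mean of n
    independent observation errors ~ N(0, gamma^2 / n).
    """
    cfg = SimConfig(T=T, R=R, seed=seed, burn_in=burn_in)
    n, gamma, w = params.n, params.gamma, params.w
    rng = np.random.default_rng(cfg.seed)
    kappa = rng.standard_normal((R, n))  # pure environmental initial estimates

    sigma_t = np.empty(T + 1)
    rho_t = np.empty(T + 1)
    burn = cfg.resolved_burn_in
    m2_acc = np.zeros(R)      # per-replicate sum of mean-square estimates
    x_acc = np.zeros(R)       # per-replicate sum of mean cross-products
    mean_acc = np.zeros(R)
    kept = 0

    def record(t: int) -> None:
        nonlocal kept
        q = kappa**2
        m2 = q.mean(axis=1)
        s = kappa.sum(axis=1)
        cross = (s**2 - q.sum(axis=1)) / (n * (n - 1))
        sigma_t[t] = np.sqrt(m2.mean())
        rho_t[t] = cross.mean() / m2.mean()
        if t > burn:
            m2_acc[:] += m2
            x_acc[:] += cross
            mean_acc[:] += kappa.mean(axis=1)
            kept += 1

    record(0)
    noise_scale = gamma / np.sqrt(n)
    for t in range(1, T + 1):
        z = rng.standard_normal((R, n))
        obs = kappa.mean(axis=1, keepdims=True) \
            + noise_scale * rng.standard_normal((R, n))
        kappa = w * z + (1.0 - w) * obs
        record(t)

    m2_r = m2_acc / kept
    x_r = x_acc / kept
    sig2_hat = m2_r.mean()
    sig2_se = m2_r.std(ddof=1) / np.sqrt(R)
    sigma_hat = float(np.sqrt(sig2_hat))
    sigma_se = float(sig2_se / (2.0 * sigma_hat))  # delta method
    rho_hat, rho_se = _ratio_stats(x_r, m2_r)
    gm = mean_acc / kept
    return SimSummary(
        sigma_t=sigma_t, rho_t=rho_t,
        sigma_hat=sigma_hat, sigma_se=sigma_se,
        rho_hat=rho_hat, rho_se=rho_se,
        grand_mean=float(gm.mean()),
        grand_mean_se=float(gm.std(ddof=1) / np.sqrt(R)),
    )


def simulate_heterogeneous(genomes: list[AgentGenome], T: int, R: int,
                           seed: int | None = None,
                           burn_in: int | None = None) -> SimSummary:
    """Simulate R independent groups with per-agent (w, epsilon, gamma).

    Agents follow the noisy group-mean estimate; agent i's observation noise
    on the mean has s.d. gamma_i / sqrt(n).  Returns pooled trajectories
    plus per-agent equilibrium errors and the empirical covariance matrix
    of estimates (time- and replicate-averaged after burn-in) with
    replicate-spread standard errors — the oracle for the analytic
    covariance fixed point.
    """
    cfg = SimConfig(T=T, R=R, seed=seed, burn_in=burn_in)
    n = len(genomes)
    w = np.array([g.w for g in genomes])
    eps = np.array([g.epsilon for g in genomes])
    gam = np.array([g.gamma for g in genomes])
    rng = np.random.default_rng(cfg.seed)
    kappa = eps * rng.standard_normal((R, n))

    sigma_t = np.empty(T + 1)
    rho_t = np.empty(T + 1)
    burn = cfg.resolved_burn_in
    outer_acc = np.zeros((R, n, n))
    kept = 0

    def record(t: int) -> None:
        nonlocal kept
        q = kappa**2
        m2 = q.mean(axis=1)
        s = kappa.sum(axis=1)
        cross = (s**2 - q.sum(axis=1)) / (n * (n - 1))
        sigma_t[t] = np.sqrt(m2.mean())
        rho_t[t] = cross.mean() / m2.mean()
        if t > burn:
            outer_acc[:] += kappa[:, :, None] * kappa[:, None, :]
            kept += 1

    record(0)
    noise_scale = gam / np.sqrt(n)
    for t in range(1, T + 1):
        z = eps * rng.standard_normal((R, n))
        obs = kappa.mean(axis=1, keepdims=True) \
            + noise_scale * rng.standard_normal((R, n))
        kappa = w * z + (1.0 - w) * obs
        record(t)

    cov_r = outer_acc / kept                    # (R, n, n) per-replicate covariances
    cov_hat = cov_r.mean(axis=0)
    cov_se = cov_r.std(axis=0, ddof=1) / np.sqrt(R)
    sigma_agent = np.sqrt(np.diag(cov_hat))
    m2_r = np.einsum("rii->r", cov_r) / n
    sig2_hat = m2_r.mean()
    sigma_hat = float(np.sqrt(sig2_hat))
    sigma_se = float((m2_r.std(ddof=1) / np.sqrt(R)) / (2.0 * sigma_hat))
    x_r = (cov_r.sum(axis=(1, 2)) - np.einsum("rii->r", cov_r)) / (n * (n - 1))
    rho_hat, rho_se = _ratio_stats(x_r, m2_r)
    return SimSummary(
        sigma_t=sigma_t, rho_t=rho_t,
        sigma_hat=sigma_hat, sigma_se=sigma_se,
        rho_hat=rho_hat, rho_se=rho_se,
        sigma_agent=sigma_agent, cov_hat=cov_hat, cov_se=cov_se,
    )


def simulate_mixed(params: MixedParams, T: int, R: int,
                   seed: int | None = None,
                   burn_in: int | None = None) -> MixedSimSummary:
    """Simulate the two-type layout: type A agents weight the observed
    type-A average by alphaA against the type-B average (likewise type B),
    with uniform observation noise gamma."""
    cfg = SimConfig(T=T, R=R, seed=seed, burn_in=burn_in)
    p = params
    nA, nB = p.nA, p.nB
    rng = np.random.default_rng(cfg.seed)
    kA = rng.standard_normal((R, nA))
    kB = p.epsilon * rng.standard_normal((R, nB))

    # per-observer noise s.d. on the alpha-weighted social average
    def noise_sd(alpha: float) -> float:
        return p.gamma * np.sqrt(alpha**2 / nA + (1.0 - alpha) ** 2 / nB)

    sA_t = np.empty(T + 1)
    sB_t = np.empty(T + 1)
    burn = cfg.resolved_burn_in
    accA2 = np.zeros(R)
    accB2 = np.zeros(R)
    accAA = np.zeros(R)
    accBB = np.zeros(R)
    accAB = np.zeros(R)
    kept = 0

    def record(t: int) -> None:
        nonlocal kept
        qA, qB = kA**2, kB**2
        m2A, m2B = qA.mean(axis=1), qB.mean(axis=1)
        sA_t[t] = np.sqrt(m2A.mean())
        sB_t[t] = np.sqrt(m2B.mean())
        if t > burn:
            sa, sb = kA.sum(axis=1), kB.sum(axis=1)
            accA2[:] += m2A
            accB2[:] += m2B
            if nA > 1:
                accAA[:] += (sa**2 - qA.sum(axis=1)) / (nA * (nA - 1))
            if nB > 1:
                accBB[:] += (sb**2 - qB.sum(axis=1)) / (nB * (nB - 1))
            accAB[:] += sa * sb / (nA * nB)
            kept += 1

    record(0)
    sdA, sdB = noise_sd(p.alphaA), noise_sd(p.alphaB)
    for t in range(1, T + 1):
        mA = kA.mean(axis=1, keepdims=True)
        mB = kB.mean(axis=1, keepdims=True)
        zA = rng.standard_normal((R, nA))
        zB = p.epsilon * rng.standard_normal((R, nB))
        socA = p.alphaA * mA + (1.0 - p.alphaA) * mB \
            + sdA * rng.standard_normal((R, nA))
        socB = p.alphaB * mA + (1.0 - p.alphaB) * mB \
            + sdB * rng.standard_normal((R, nB))
        kA = p.wA * zA + (1.0 - p.wA) * socA
        kB = p.wB * zB + (1.0 - p.wB) * socB
        record(t)

    m2A_r, m2B_r = accA2 / kept, accB2 / kept
    sA2, sB2 = m2A_r.mean(), m2B_r.mean()
    sA_hat, sB_hat = float(np.sqrt(sA2)), float(np.sqrt(sB2))
    sA_se = float((m2A_r.std(ddof=1) / np.sqrt(R)) / (2 * sA_hat))
    sB_se = float((m2B_r.std(ddof=1) / np.sqrt(R)) / (2 * sB_hat))
    rAA = float((accAA / kept).mean() / sA2) if nA > 1 else float("nan")
    rBB = float((accBB / kept).mean() / sB2) if nB > 1 else float("nan")
    rAB, rAB_se = _ratio_stats(accAB / kept, np.sqrt(m2A_r * m2B_r))
    return MixedSimSummary(
        sigmaA_t=sA_t, sigmaB_t=sB_t,
        sigmaA_hat=sA_hat, sigmaA_se=sA_se,
        sigmaB_hat=sB_hat, sigmaB_se=sB_se,
        rhoAA_hat=rAA, rhoBB_hat=rBB, rhoAB_hat=rAB, rhoAB_se=rAB_se,
    )
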