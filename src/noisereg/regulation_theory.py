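"""Fitness theory of gene regulation in fluctuating environments.

A single gene experiences an ensemble of environments e, each with a desired
log-expression level mu_e and a Gaussian fitness window of width tau.  An
unregulated promoter has Gaussian expression with mean mu and variance
sigma^2; its environment-averaged log-fitness is

    log f = -[(mu - <mu_e>)^2 + var(mu_e)] / (2 (tau^2 + sigma^2))
            + (1/2) log[tau^2 / (tau^2 + sigma^2)].

Coupling the promoter linearly to a regulator (mean activity r_e per
environment, within-environment activity variance sigma_r^2, coupling
constant c) has two effects: the condition-response (the target's mean
tracks c*r_e) and noise-propagation (the target's variance grows by
c^2*sigma_r^2).  With the basal mean optimized, the log-fitness gain of the
new interaction depends on only four dimensionless parameters --

    X^2 = c^2 sigma_r^2 / (sigma^2 + tau^2)   (renormalized coupling)
    Y^2 = var(mu_e)     / (sigma^2 + tau^2)   (expression mismatch)
    S^2 = var(r_e)      / sigma_r^2           (regulator signal-to-noise)
    R   = corr(mu_e, r_e)                     (regulator correlation)

-- through the closed form

    d log f = (1/2) [(X^2 + R^2) Y^2 - (S X - R Y)^2] / (1 + X^2)
              - (1/2) log(1 + X^2).

Its optima are analytic: S* = R Y / X and X*^2 = max[0, (1-R^2) Y^2 - 1].
The locus (1-R^2) Y^2 = 1 is a phase boundary: above it (accurate
regulation) the promoter keeps its basal noise; below it noise-propagation
is positively selected and the optimal total noise is
sigma_tot^2 = (1-R^2) var(mu_e) - tau^2.

Sign convention: X is non-negative; a repressive coupling (c < 0) is
represented by flipping the sign of the effective correlation, since the
gain depends on c only through X^2 and the product S*X - R*Y.

Log-fitness values are reported up to an environment-independent additive
constant; only differences are contract-bearing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "EnvironmentEnsemble",
    "RegulatorProfile",
    "CouplingState",
    "ResidualState",
    "mismatch_Y",
    "regulator_RS",
    "logfitness_unregulated",
    "logfitness_coupled",
    "dlogf",
    "dlogf_constructive",
    "coupling_state",
    "optimal_coupling",
    "optimal_signal_to_noise",
    "predicted_total_noise",
    "composite_regulator",
    "iterate_regulation",
    "maximize_dlogf",
    "optimal_sigma2_unregulated",
    "fitness_landscape",
]


def _weighted_mean_var(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    m = float(np.sum(w * x))
    return m, float(np.sum(w * (x - m) ** 2))


@dataclass(frozen=True)
class EnvironmentEnsemble:
    """Desired log-expression levels mu_e with a Gaussian fitness width tau.

    ``weights`` are per-environment frequencies (uniform by default, summing
    to 1); the log-fitness of a genotype is the weighted mean of its
    per-environment log-fitness.
    """

    mu_e: np.ndarray
    tau: float
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu_e", np.atleast_1d(np.asarray(self.mu_e, float)))
        if self.mu_e.size < 1:
            raise ValueError("need at least one environment")
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.weights is None:
            w = np.full(self.mu_e.size, 1.0 / self.mu_e.size)
        else:
            w = np.asarray(self.weights, float)
            if w.shape != self.mu_e.shape or np.any(w < 0):
                raise ValueError("weights must be non-negative and aligned with mu_e")
            if not np.isclose(w.sum(), 1.0):
                raise ValueError("weights must sum to 1")
        object.__setattr__(self, "weights", w)

    @property
    def n_environments(self) -> int:
        return int(self.mu_e.size)

    @property
    def mean_mu_e(self) -> float:
        return _weighted_mean_var(self.mu_e, self.weights)[0]

    @property
    def var_mu_e(self) -> float:
        return _weighted_mean_var(self.mu_e, self.weights)[1]


@dataclass(frozen=True)
class RegulatorProfile:
    """Mean regulator activity per environment plus within-environment noise.

    ``r_e`` aligns with an :class:`EnvironmentEnsemble`; the activity in
    environment e is Gaussian with mean ``r_e[e]`` and variance ``sigma_r2``
    (held constant across environments in the closed forms).
    """

    r_e: np.ndarray
    sigma_r2: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "r_e", np.atleast_1d(np.asarray(self.r_e, float)))
        if not self.sigma_r2 > 0:
            raise ValueError(f"sigma_r2 must be > 0, got {self.sigma_r2}")


@dataclass(frozen=True)
class CouplingState:
    """Dimensionless description of one promoter-regulator coupling."""

    mu: float
    sigma2: float
    c: float
    X: float
    Y: float
    R: float
    S: float


@dataclass(frozen=True)
class ResidualState:
    """State after absorbing one regulatory interaction.

    mu_e_residual = mu_e - c * r_e, sigma2_new = sigma^2 + c^2 sigma_r^2,
    and Y_new is the mismatch recomputed on the residuals.
    """

    mu_e_residual: np.ndarray
    sigma2_new: float
    Y_new: float


def mismatch_Y(env: EnvironmentEnsemble, sigma2: float) -> float:
    """Expression mismatch Y = sqrt(var(mu_e) / (sigma^2 + tau^2))."""
    return float(np.sqrt(env.var_mu_e / (sigma2 + env.tau**2)))


def regulator_RS(env: EnvironmentEnsemble, reg: RegulatorProfile) -> tuple[float, float]:
    """Correlation R of r_e with mu_e, and signal-to-noise S of the regulator.

    R is the (weighted) Pearson correlation; S^2 = var(r_e) / sigma_r^2.
    When r_e (or mu_e) has zero variance, R is undefined: NaN is returned
    with a warning, and S = 0 for constant r_e.
    """
    if env.n_environments < 2:
        raise ValueError("need >= 2 environments to define a correlation")
    if reg.r_e.shape != env.mu_e.shape:
        raise ValueError("regulator profile not aligned with environment ensemble")
    w = env.weights
    _, var_mu = _weighted_mean_var(env.mu_e, w)
    mean_r, var_r = _weighted_mean_var(reg.r_e, w)
    S = float(np.sqrt(var_r / reg.sigma_r2))
    if var_r == 0.0 or var_mu == 0.0:
        warnings.warn("zero variance in r_e or mu_e: correlation R is undefined")
        return float("nan"), S
    cov = float(np.sum(w * (env.mu_e - env.mean_mu_e) * (reg.r_e - mean_r)))
    R = cov / np.sqrt(var_mu * var_r)
    return float(np.clip(R, -1.0, 1.0)), S


def logfitness_unregulated(mu: float, sigma2: float, env: EnvironmentEnsemble) -> float:
    """Environment-averaged log-fitness of an unregulated promoter.

    Equals the weighted mean over environments of the log of the Gaussian
    genotype fitness; maximized over mu at mu = <mu_e>.
    """
    d = env.tau**2 + sigma2
    mean_mu, var_mu = _weighted_mean_var(env.mu_e, env.weights)
    return float(-((mu - mean_mu) ** 2 + var_mu) / (2.0 * d) + 0.5 * np.log(env.tau**2 / d))


def logfitness_coupled(
    mu: float,
    sigma2: float,
    c: float,
    env: EnvironmentEnsemble,
    reg: RegulatorProfile,
) -> float:
    """Log-fitness of a promoter linearly coupled to a regulator.

    The promoter's mean in environment e is mu + c*r_e and its total
    variance is sigma^2 + c^2*sigma_r^2.  Reduces to
    :func:`logfitness_unregulated` at c = 0.
    """
    if reg.r_e.shape != env.mu_e.shape:
        raise ValueError("regulator profile not aligned with environment ensemble")
    d = env.tau**2 + sigma2 + c**2 * reg.sigma_r2
    dev2 = float(np.sum(env.weights * (mu + c * reg.r_e - env.mu_e) ** 2))
    return float(-dev2 / (2.0 * d) + 0.5 * np.log(env.tau**2 / d))


def dlogf(X: float, Y: float, R: float, S: float) -> float:
    """Closed-form log-fitness gain of a new regulatory interaction.

    ``X >= 0`` (repression is absorbed into the sign of R).  Zero at X = 0.
    """
    if X < 0:
        raise ValueError("X must be >= 0 (absorb the sign of c into R)")
    if X == 0:
        return 0.0
    x2 = X * X
    return float(
        0.5 * ((x2 + R * R) * Y * Y - (S * X - R * Y) ** 2) / (1.0 + x2)
        - 0.5 * np.log1p(x2)
    )


def coupling_state(
    mu: float,
    sigma2: float,
    c: float,
    env: EnvironmentEnsemble,
    reg: RegulatorProfile,
) -> CouplingState:
    """Map a constructive (env, regulator, coupling) system to (X, Y, R, S).

    X is non-negative; the sign of c is absorbed into the effective
    correlation R -> sign(c) * R.
    """
    d = sigma2 + env.tau**2
    R, S = regulator_RS(env, reg)
    X = abs(c) * np.sqrt(reg.sigma_r2 / d)
    R_eff = np.sign(c) * R if c != 0 else R
    return CouplingState(mu, sigma2, c, float(X), mismatch_Y(env, sigma2), float(R_eff), S)


def dlogf_constructive(
    sigma2: float, c: float, env: EnvironmentEnsemble, reg: RegulatorProfile
) -> float:
    """Log-fitness gain computed from the constructive path (the oracle side).

    Difference of :func:`logfitness_coupled` and
    :func:`logfitness_unregulated`, each at its own optimal basal mean
    (mu = <mu_e> - c<r_e> and mu = <mu_e>).  Agrees with :func:`dlogf`
    evaluated at the corresponding (X, Y, R, S).
    """
    mean_r = float(np.sum(env.weights * reg.r_e))
    mu_opt = env.mean_mu_e - c * mean_r
    return logfitness_coupled(mu_opt, sigma2, c, env, reg) - logfitness_unregulated(
        env.mean_mu_e, sigma2, env
    )


def optimal_coupling(Y: float, R: float) -> float:
    """Optimal renormalized coupling X* = sqrt(max[0, (1-R^2) Y^2 - 1]).

    Zero whenever the residual mismatch (1-R^2) Y^2 is below 1 (the basal
    noise regime).
    """
    return float(np.sqrt(max(0.0, (1.0 - R * R) * Y * Y - 1.0)))


def optimal_signal_to_noise(R: float, Y: float, X: float) -> float:
    """Optimal regulator signal-to-noise S* = R Y / X at fixed coupling.

    Undefined at X = 0 (S* diverges at the phase boundary).
    """
    if X == 0:
        raise ValueError("S* is undefined at X = 0 (diverges at the phase boundary)")
    return float(R * Y / X)


def predicted_total_noise(R: float, env: EnvironmentEnsemble, sigma2: float) -> float:
    """Optimal total noise sigma_tot^2 of a promoter coupled at (X*, S*).

    Returns the basal sigma^2 in the basal-noise regime
    (1-R^2) Y^2 <= 1, and (1-R^2) var(mu_e) - tau^2 in the
    environment-driven regime; continuous across the phase boundary.
    """
    Y = mismatch_Y(env, sigma2)
    if (1.0 - R * R) * Y * Y <= 1.0:
        return float(sigma2)
    return float((1.0 - R * R) * env.var_mu_e - env.tau**2)


def composite_regulator(
    regs: Sequence[RegulatorProfile],
    couplings: Sequence[float],
    cross_correlations: np.ndarray | None = None,
    effective_c: float = 1.0,
    weight_cross_by_couplings: bool = False,
) -> RegulatorProfile:
    """Collapse a linear combination of regulators into one effective one.

    The combination sum_i c_i r_e^i, coupled with constant ``effective_c``,
    has mean activity r_e = sum_i c_i r_e^i / effective_c and variance

        sigma_r^2 = sum_i c_i^2 sigma_i^2 + sum_{i != j} R_ij sigma_i sigma_j

    with R_ij the cross-correlation of regulator fluctuations (identity by
    default, i.e. independent regulators).  ``weight_cross_by_couplings``
    switches the cross term to c_i c_j R_ij sigma_i sigma_j, the variant in
    which the off-diagonal term carries the same coupling factors as the
    diagonal one.
    """
    regs = list(regs)
    c = np.asarray(couplings, float)
    if len(regs) != c.size:
        raise ValueError("one coupling per regulator required")
    n = len(regs)
    shapes = {r.r_e.shape for r in regs}
    if len(shapes) != 1:
        raise ValueError("regulators must share the environment list")
    if cross_correlations is None:
        corr = np.eye(n)
    else:
        corr = np.asarray(cross_correlations, float)
        if corr.shape != (n, n):
            raise ValueError("cross_correlations must be n x n")
        if not np.allclose(corr, corr.T):
            raise ValueError("cross_correlations must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("cross_correlations must have unit diagonal")
        if np.min(np.linalg.eigvalsh(corr)) < -1e-10:
            raise ValueError("cross_correlations must be positive semidefinite")

    r_e = sum(ci * r.r_e for ci, r in zip(c, regs)) / effective_c
    sig = np.array([np.sqrt(r.sigma_r2) for r in regs])
    var = float(np.sum(c**2 * sig**2))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            term = corr[i, j] * sig[i] * sig[j]
            if weight_cross_by_couplings:
                term *= c[i] * c[j]
            var += term
    return RegulatorProfile(r_e, var)


def iterate_regulation(
    env: EnvironmentEnsemble,
    reg: RegulatorProfile,
    c: float,
    sigma2: float,
) -> ResidualState:
    """Absorb one regulatory interaction and return the residual problem.

    The next interaction sees desired levels mu_e - c*r_e and promoter
    variance sigma^2 + c^2*sigma_r^2; applying :func:`dlogf` with the
    returned ``Y_new`` gives the gain of a second interaction.
    """
    if reg.r_e.shape != env.mu_e.shape:
        raise ValueError("regulator profile not aligned with environment ensemble")
    residual = env.mu_e - c * reg.r_e
    sigma2_new = sigma2 + c**2 * reg.sigma_r2
    _, var_res = _weighted_mean_var(residual, env.weights)
    y_new = float(np.sqrt(var_res / (sigma2_new + env.tau**2)))
    return ResidualState(residual, float(sigma2_new), y_new)


def optimal_sigma2_unregulated(
    env: EnvironmentEnsemble, sigma2_max: float | None = None, xatol: float = 1e-10
) -> float:
    """Numeric argmax over sigma^2 of the unregulated log-fitness.

    The bet-hedging optimum: 0 when var(mu_e) < tau^2, else
    var(mu_e) - tau^2.  Computed here by bounded 1-D maximization (the
    closed form is what tests compare against).
    """
    if sigma2_max is None:
        sigma2_max = 10.0 * (env.var_mu_e + env.tau**2) + 1.0
    res = optimize.minimize_scalar(
        lambda s2: -logfitness_unregulated(env.mean_mu_e, s2, env),
        bounds=(0.0, sigma2_max),
        method="bounded",
        options={"xatol": xatol},
    )
    # the boundary sigma2 = 0 competes with any interior point
    if logfitness_unregulated(env.mean_mu_e, 0.0, env) >= -res.fun:
        return 0.0
    return float(res.x)


def _max_over_S(X: float, Y: float, R: float, xatol: float = 1e-12) -> tuple[float, float]:
    """Numeric max over S of dlogf at fixed (X, Y, R)."""
    b = max(10.0, 3.0 * abs(R) * Y / max(X, 1e-9) + 1.0)
    res = optimize.minimize_scalar(
        lambda S: -dlogf(X, Y, R, S), bounds=(-b, b), method="bounded",
        options={"xatol": xatol},
    )
    return float(res.x), float(-res.fun)


def maximize_dlogf(
    Y: float, R: float, x_hi: float | None = None
) -> tuple[float, float, float]:
    """Joint numeric maximization of dlogf over (X >= 0, S).

    Nested bounded 1-D searches (outer over X, inner over S) followed by a
    joint Nelder-Mead polish.  Returns ``(gain, X_opt, S_opt)``.  In the
    basal-noise regime the supremum sits on the X -> 0 boundary (jointly
    with S -> infinity); the returned X is then numerically 0 and S is the
    inner optimum at that X.
    """
    if x_hi is None:
        x_hi = 3.0 * optimal_coupling(Y, R) + 10.0

    def profile(X: float) -> float:
        return _max_over_S(X, Y, R)[1]

    res = optimize.minimize_scalar(
        lambda X: -profile(X), bounds=(1e-9, x_hi), method="bounded",
        options={"xatol": 1e-11},
    )
    x0 = float(res.x)
    s0 = _max_over_S(x0, Y, R)[0]
    polish = optimize.minimize(
        lambda p: -dlogf(abs(p[0]), Y, R, p[1]),
        x0=[x0, s0],
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 2000},
    )
    if -polish.fun >= -res.fun:
        x_opt, s_opt = abs(float(polish.x[0])), float(polish.x[1])
        val = float(-polish.fun)
    else:
        x_opt, s_opt, val = x0, s0, float(-res.fun)
    return val, x_opt, s_opt


def _max_over_X(Y: float, R: float, S: float, x_hi: float) -> float:
    """Numeric max over X >= 0 of dlogf at fixed (Y, R, S)."""
    res = optimize.minimize_scalar(
        lambda X: -dlogf(X, Y, R, S), bounds=(0.0, x_hi), method="bounded",
        options={"xatol": 1e-9},
    )
    return float(max(-res.fun, 0.0))  # X = 0 (gain 0) is always available


def fitness_landscape(
    Y: float, R_grid: Sequence[float], S_grid: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Max-over-coupling log-fitness gain on an (R, S) grid, plus the ridge.

    Returns ``(gain, ridge)`` where ``gain[i, j]`` is the maximum over
    X >= 0 of dlogf at ``(R_grid[i], S_grid[j])`` and ``ridge[i]`` is the
    optimal signal-to-noise S*(R_i) at the optimal coupling for this Y
    (NaN where the optimal coupling is 0 and S* diverges).
    """
    R_grid = np.asarray(R_grid, float)
    S_grid = np.asarray(S_grid, float)
    if R_grid.size == 0 or S_grid.size == 0:
        raise ValueError("grids must be non-empty")
    x_hi = 3.0 * Y + 10.0
    gain = np.empty((R_grid.size, S_grid.size))
    for i, R in enumerate(R_grid):
        for j, S in enumerate(S_grid):
            gain[i, j] = _max_over_X(Y, R, S, x_hi)
    ridge = np.empty(R_grid.size)
    for i, R in enumerate(R_grid):
        xs = optimal_coupling(Y, R)
        ridge[i] = R * Y / xs if xs > 0 else np.nan
    return gain, ridge
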