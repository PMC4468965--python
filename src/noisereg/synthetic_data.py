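"""Synthetic data with the statistical structure the analyses assume.

Generators for every input of the pipeline: log-normal per-genotype
expression samples whose variance is the mean-variance floor plus planted
excess noise; environment ensembles and regulator activity profiles with
prescribed correlation R and signal-to-noise S (exact by construction via
orthogonalization); binary regulatory networks with planted
noise-propagation strengths; and per-gene condition log fold-change tables
whose variance is coupled to planted excess, so association curves have a
known monotone or flat shape.

Every generator is deterministic given its seed, and ground truth is
returned alongside each dataset.

Default study conditions: floor parameters (sigma_ab2, beta) = (0.025, 450)
with background 100 GFP molecules; 480 promoters measured over 5000 cells
each, with mean log-expression spanning the medium-to-high window around
the selection target mu* = 8.1; planted excess noise drawn from an
exponential of mean 0.08 on a random half of the promoters (long-tailed,
like native excess distributions); a 1000-promoter x 20-regulator network
at edge probability 0.1 with exponential(0.05) propagation strengths and
Gaussian noise at twice the signal SD; 240 plasticity conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .noise_model import FlowSample, NoiseFloorParams, PromoterRecord, minimal_variance
from .regulation_theory import EnvironmentEnsemble, RegulatorProfile, regulator_RS

__all__ = [
    "SyntheticSpec",
    "gen_flow_populations",
    "gen_environment_and_regulator",
    "gen_network",
    "gen_plasticity",
]


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic datasets (see module docstring)."""

    seed: int = 0
    # flow populations
    n_promoters: int = 480
    n_cells: int = 5000
    floor_params: NoiseFloorParams = field(
        default_factory=lambda: NoiseFloorParams(0.025, 450.0, 100.0)
    )
    mean_log_range: tuple[float, float] = (6.5, 9.5)
    excess_mean: float = 0.08
    excess_fraction: float = 0.5
    outlier_fraction: float = 0.0
    outlier_sd_multiple: float = 10.0
    # environments / regulators
    n_environments: int = 3
    tau: float = 0.03
    mu_star: float = 8.1
    # network
    n_network_promoters: int = 1000
    n_regulators: int = 20
    edge_probability: float = 0.1
    v_true_mean: float = 0.05
    noise_sd_multiple: float = 2.0
    # plasticity
    n_conditions: int = 240
    plasticity_baseline: float = 0.3
    plasticity_coupling: float = 3.0

    def __post_init__(self) -> None:
        if self.n_promoters < 1 or self.n_regulators < 1 or self.n_conditions < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.excess_fraction <= 1.0:
            raise ValueError("excess_fraction must be in [0, 1]")
        if self.excess_mean < 0:
            raise ValueError("excess_mean must be >= 0")


def gen_flow_populations(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[list[FlowSample], list[PromoterRecord]]:
    """Per-promoter flow samples plus exact ground-truth records.

    Mean log-expression is uniform over ``spec.mean_log_range``; the true
    variance is the floor at that mean plus a planted excess (exponential
    of mean ``excess_mean`` on a random ``excess_fraction`` of promoters,
    exactly zero elsewhere); per-cell log values are Gaussian, optionally
    contaminated with ``outlier_fraction`` gross outliers at
    ``+-outlier_sd_multiple`` sample SDs.  Ground-truth records carry the
    true moments and planted excess.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n = spec.n_promoters
    mean_log = rng.uniform(*spec.mean_log_range, size=n)
    floor = np.atleast_1d(minimal_variance(np.exp(mean_log), spec.floor_params))
    has_excess = rng.random(n) < spec.excess_fraction
    excess = np.where(has_excess, rng.exponential(spec.excess_mean, size=n), 0.0)
    var_log = floor + excess

    samples, truth = [], []
    for i in range(n):
        pid = f"synth_{i:04d}"
        vals = rng.normal(mean_log[i], np.sqrt(var_log[i]), size=spec.n_cells)
        if spec.outlier_fraction > 0:
            n_out = rng.binomial(spec.n_cells, spec.outlier_fraction)
            if n_out:
                pos = rng.choice(spec.n_cells, size=n_out, replace=False)
                signs = rng.choice([-1.0, 1.0], size=n_out)
                vals[pos] = mean_log[i] + signs * spec.outlier_sd_multiple * np.sqrt(var_log[i])
        samples.append(FlowSample(pid, vals))
        truth.append(
            PromoterRecord(pid, float(mean_log[i]), float(var_log[i]),
                           n_cells=spec.n_cells, excess_noise=float(excess[i]))
        )
    return samples, truth


def gen_environment_and_regulator(
    mu_e: np.ndarray,
    tau: float,
    target_R: float,
    target_S: float,
    rng: np.random.Generator,
    activity_sd: float = 1.0,
) -> tuple[EnvironmentEnsemble, RegulatorProfile]:
    """Environment ensemble plus a regulator hitting (R, S) exactly.

    The regulator's mean activities are built as
    ``r_e = R * z + sqrt(1 - R^2) * eta`` where z is the standardized
    mu_e profile and eta is random noise orthogonalized against z and the
    constant (so the realized sample correlation equals ``target_R``
    exactly, for any number of environments >= 3), scaled to SD
    ``activity_sd``; the within-environment variance is then
    ``var(r_e) / target_S**2``.
    """
    mu_e = np.asarray(mu_e, float)
    if mu_e.size < 3:
        raise ValueError("need >= 3 environments for a nontrivial correlation")
    if abs(target_R) > 1:
        raise ValueError(f"|R| must be <= 1, got {target_R}")
    if not target_S > 0:
        raise ValueError("target S must be > 0")
    env = EnvironmentEnsemble(mu_e, tau)

    dev = mu_e - mu_e.mean()
    if np.allclose(dev, 0):
        raise ValueError("mu_e must vary across environments to target a correlation")
    z = dev / dev.std()

    if abs(target_R) == 1.0:
        r = np.sign(target_R) * z * activity_sd
    else:
        eta = rng.normal(size=mu_e.size)
        eta = eta - eta.mean()
        eta = eta - (eta @ z) / (z @ z) * z
        if np.allclose(eta, 0):  # pathological draw; retry deterministically
            eta = np.arange(mu_e.size) - (mu_e.size - 1) / 2.0
            eta = eta - (eta @ z) / (z @ z) * z
        eta = eta / eta.std()
        r = (target_R * z + np.sqrt(1.0 - target_R**2) * eta) * activity_sd

    var_r = float(r.var())
    sigma_r2 = var_r / target_S**2
    reg = RegulatorProfile(r, sigma_r2)
    return env, reg


def gen_network(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple["RegulatoryMatrix", np.ndarray, np.ndarray]:
    """Binary incidence matrix, planted strengths V_true, and noisy excess.

    Edges are Bernoulli(``edge_probability``); V_true is exponential with
    mean ``v_true_mean`` (non-negative, long-tailed); the emitted excess is
    ``E = M V_true + noise`` with Gaussian noise of SD
    ``noise_sd_multiple`` times the signal SD.
    """
    from .propagation_regression import RegulatoryMatrix

    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n, p = spec.n_network_promoters, spec.n_regulators
    entries = (rng.random((n, p)) < spec.edge_probability).astype(int)
    M = RegulatoryMatrix(
        [f"p{i:04d}" for i in range(n)], [f"tf{j:02d}" for j in range(p)], entries
    )
    v_true = rng.exponential(spec.v_true_mean, size=p)
    signal = entries @ v_true
    noise_sd = spec.noise_sd_multiple * float(signal.std())
    E = signal + rng.normal(0.0, noise_sd, size=n)
    return M, v_true, E


def gen_plasticity(
    excess: np.ndarray,
    gene_ids: list[str] | None = None,
    coupling_to_excess: float = 3.0,
    baseline: float = 0.3,
    n_conditions: int = 240,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Condition log fold-change matrix with plasticity coupled to excess.

    Gene g's log fold-changes are N(0, baseline + coupling * max(excess, 0))
    over ``n_conditions`` conditions, so the cutoff running-mean curve of
    plasticity against excess noise is monotone increasing for positive
    coupling and flat at coupling 0.  Returns a genes x conditions frame
    indexed by gene id.
    """
    if n_conditions < 2:
        raise ValueError("need >= 2 conditions")
    rng = np.random.default_rng(seed) if rng is None else rng
    excess = np.asarray(excess, float)
    if gene_ids is None:
        gene_ids = [f"gene_{i:04d}" for i in range(excess.size)]
    var = baseline + coupling_to_excess * np.clip(excess, 0.0, None)
    vals = rng.normal(0.0, 1.0, size=(excess.size, n_conditions)) * np.sqrt(var)[:, None]
    return pd.DataFrame(vals, index=pd.Index(gene_ids, name="gene_id"),
                        columns=[f"cond_{j:03d}" for j in range(n_conditions)])
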