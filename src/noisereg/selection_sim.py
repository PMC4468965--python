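"""FACS sort-and-mutate evolution on phenotype-level promoter populations.

The sorter is modeled as a Gaussian selection function: a cell with
log-expression x passes the gate with probability

    f(x | mu*, tau) = exp[-(x - mu*)^2 / (2 tau^2)]

with mu* the target log-expression and tau the gate width.  Integrating over
a genotype's (Gaussian) expression distribution with mean mu and variance
sigma^2 gives the genotype fitness, i.e. the expected fraction of its cells
that the sorter keeps:

    f(mu, sigma | mu*, tau) = sqrt(tau^2 / (tau^2 + sigma^2))
                              * exp[-(mu - mu*)^2 / (2 (tau^2 + sigma^2))]

Evolution is simulated at the phenotype level: each lineage carries a mean
log-expression and a noise phenotype; rounds alternate cell-level sorting
(probabilistic acceptance by the selection function, or a rank/top-k gate)
with mutation.  When noise-floor parameters are supplied, a lineage's total
variance is the physical floor at its mean plus a heritable excess-noise
trait; mutation rescales existing excess multiplicatively and therefore
cannot push a lineage below the floor (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .noise_model import NoiseFloorParams, minimal_variance

__all__ = [
    "SelectionGate",
    "PromoterGenotype",
    "Population",
    "MutationKernel",
    "EvolutionTrajectory",
    "selection_prob",
    "genotype_fitness",
    "evolve_population",
    "constant_gate_schedule",
]

#: Floor on the excess-noise trait below which a lineage is treated as
#: exactly on the minimal-variance curve.
_EXCESS_EPS = 1e-12


@dataclass(frozen=True)
class SelectionGate:
    """Gaussian FACS gate: target log-expression mu_star, width tau (>0)."""

    mu_star: float
    tau: float

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")


def constant_gate_schedule(gate: SelectionGate, n_rounds: int) -> list[SelectionGate]:
    """Per-round gate list with the same gate each round."""
    return [gate] * n_rounds


@dataclass(frozen=True)
class PromoterGenotype:
    """A promoter phenotype: mean log-expression and variance (log scale)."""

    mu: float
    sigma2: float

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError(f"sigma2 must be >= 0, got {self.sigma2}")


@dataclass
class Population:
    """Genotype list with abundances."""

    mus: np.ndarray
    sigma2s: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.mus = np.asarray(self.mus, dtype=float)
        self.sigma2s = np.asarray(self.sigma2s, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if not (self.mus.shape == self.sigma2s.shape == self.counts.shape):
            raise ValueError("mus, sigma2s and counts must have equal length")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("population must contain at least one cell")
        if np.any(self.sigma2s < 0):
            raise ValueError("sigma2 must be >= 0")

    @classmethod
    def from_genotypes(
        cls, genotypes: Sequence[PromoterGenotype], counts: Sequence[int]
    ) -> "Population":
        return cls(
            np.array([g.mu for g in genotypes]),
            np.array([g.sigma2 for g in genotypes]),
            np.asarray(counts),
        )

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_genotypes(self) -> int:
        return int(self.mus.size)

    def genotypes(self) -> list[PromoterGenotype]:
        return [PromoterGenotype(m, s) for m, s in zip(self.mus, self.sigma2s)]


@dataclass(frozen=True)
class MutationKernel:
    """Phenotype-level stand-in for PCR mutagenesis of promoter sequences.

    Each lineage receives a Poisson number of effective mutation events per
    round, with zero-event probability ``1 - p_mutate`` (the default
    ``p_mutate = 1 - e^-2`` matches a Poisson mean of 2 events, so ~95% of
    lineages carry 0-4 events per round, mirroring a 0.01/bp mutagenesis of
    a 200 bp promoter).  Each event perturbs the mean by N(0, rate_mu^2) and
    the log of the noise trait by N(0, rate_sigma^2) -- the noise trait is
    the excess above the floor when floor parameters are supplied to
    :func:`evolve_population`, the total variance otherwise.
    """

    rate_mu: float = 0.1
    rate_sigma: float = 0.3
    p_mutate: float = 1.0 - math.exp(-2.0)

    def __post_init__(self) -> None:
        if self.rate_mu < 0 or self.rate_sigma < 0:
            raise ValueError("mutation rates must be >= 0")
        if not 0.0 <= self.p_mutate <= 1.0:
            raise ValueError(f"p_mutate must be in [0, 1], got {self.p_mutate}")

    @property
    def mean_events(self) -> float:
        """Poisson mean of effective mutation events per lineage per round."""
        if self.p_mutate >= 1.0:
            return np.inf
        return -math.log1p(-self.p_mutate)


@dataclass
class EvolutionTrajectory:
    """Per-round populations plus a tidy summary table.

    Summary columns: round, mean_mu, var_mu, mean_sigma2, mean_abs_dev,
    mean_excess (NaN without floor params), expected_fraction and
    selected_fraction (NaN for the initial row).
    """

    populations: list[Population]
    summary: pd.DataFrame


def selection_prob(x, gate: SelectionGate):
    """Probability that a cell with log-expression x passes the gate."""
    x = np.asarray(x, dtype=float)
    out = np.exp(-((x - gate.mu_star) ** 2) / (2.0 * gate.tau**2))
    return out if out.ndim else float(out)


def genotype_fitness(mu, sigma2, gate: SelectionGate):
    """Expected selected fraction of a genotype (exact Gaussian integral).

    Accepts scalars or aligned arrays of (mu, sigma2).
    """
    mu = np.asarray(mu, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 < 0):
        raise ValueError("sigma2 must be >= 0")
    tot = gate.tau**2 + sigma2
    out = np.sqrt(gate.tau**2 / tot) * np.exp(-((mu - gate.mu_star) ** 2) / (2.0 * tot))
    return out if out.ndim else float(out)


def _summary_row(
    rnd: int,
    mus: np.ndarray,
    sigma2s: np.ndarray,
    weights: np.ndarray,
    gate: SelectionGate,
    floor_params: NoiseFloorParams | None,
    excess: np.ndarray | None,
) -> dict:
    w = weights / weights.sum()
    mean_mu = float(np.sum(w * mus))
    row = {
        "round": rnd,
        "mean_mu": mean_mu,
        "var_mu": float(np.sum(w * (mus - mean_mu) ** 2)),
        "mean_sigma2": float(np.sum(w * sigma2s)),
        "mean_abs_dev": float(np.sum(w * np.abs(mus - gate.mu_star))),
        "mean_excess": float(np.sum(w * excess)) if excess is not None else np.nan,
        "expected_fraction": float(
            np.sum(w * genotype_fitness(mus, sigma2s, gate))
        ),
        "selected_fraction": np.nan,
    }
    return row


def evolve_population(
    pop: Population,
    gates: Sequence[SelectionGate],
    kernel: MutationKernel,
    cells_sampled: int,
    cells_selected: int,
    seed: int,
    mode: str = "probabilistic",
    floor_params: NoiseFloorParams | None = None,
) -> EvolutionTrajectory:
    """Simulate rounds of FACS selection and mutation.

    Per round: draw ``cells_sampled`` cell-level expression values from the
    genotype distributions in proportion to counts; keep cells either with
    probability :func:`selection_prob` (``mode="probabilistic"``, the scheme
    whose expectation is the closed-form genotype fitness) or as the
    ``cells_selected`` cells closest to the target (``mode="rank"``, the
    literal top-5% gate); the kept cells found the next generation, which is
    then mutated.  Selection itself never creates genotypes: mutation is the
    only source of novelty.

    When ``floor_params`` is given, each lineage's variance is
    ``floor(exp(mu)) + excess`` with heritable ``excess >= 0``; the summary
    then reports the population mean excess noise per round.

    Returns a trajectory that is bit-reproducible given ``seed``.
    """
    if len(gates) == 0:
        raise ValueError("need at least one per-round gate")
    if cells_selected > cells_sampled:
        raise ValueError("cells_selected must be <= cells_sampled")
    if mode not in ("probabilistic", "rank"):
        raise ValueError(f"unknown selection mode {mode!r}")

    rng = np.random.default_rng(seed)

    mus = pop.mus.copy()
    sigma2s = pop.sigma2s.copy()
    counts = pop.counts.copy()
    if floor_params is not None:
        floor = minimal_variance(np.exp(mus), floor_params)
        excess = sigma2s - floor
        if np.any(excess < -1e-9):
            raise ValueError("population contains sigma2 below the noise floor")
        excess = np.clip(excess, 0.0, None)
    else:
        excess = None

    populations = [Population(mus.copy(), sigma2s.copy(), counts.copy())]
    rows = [_summary_row(0, mus, sigma2s, counts.astype(float), gates[0], floor_params, excess)]

    for rnd, gate in enumerate(gates, start=1):
        # --- sample cells from the genotype pool
        probs = counts / counts.sum()
        idx = rng.choice(mus.size, size=cells_sampled, p=probs)
        x = rng.normal(mus[idx], np.sqrt(sigma2s[idx]))

        # --- sort
        p = selection_prob(x, gate)
        if mode == "probabilistic":
            keep = rng.random(cells_sampled) < p
        else:
            order = np.argsort(np.abs(x - gate.mu_star), kind="stable")
            keep = np.zeros(cells_sampled, dtype=bool)
            keep[order[:cells_selected]] = True
        n_kept = int(keep.sum())
        if n_kept == 0:
            raise RuntimeError(
                "no cells passed the gate; widen tau or sample more cells"
            )
        sel = idx[keep]

        # --- the kept cells found the next generation (cell-level lineages)
        cell_mus = mus[sel]
        if excess is not None:
            cell_exc = excess[sel]
        else:
            cell_sigma2 = sigma2s[sel]

        # --- mutation: Poisson number of effective events per lineage
        if kernel.p_mutate >= 1.0:
            k = 1 + rng.poisson(1.0, size=n_kept)
        else:
            k = rng.poisson(kernel.mean_events, size=n_kept)
        scale = np.sqrt(k.astype(float))
        cell_mus = cell_mus + rng.normal(0.0, 1.0, n_kept) * kernel.rate_mu * scale
        if floor_params is not None and floor_params.n_bg > 0:
            # expression cannot drift below detectability over background
            cell_mus = np.maximum(cell_mus, np.log(1.05 * floor_params.n_bg))
        noise_shift = rng.normal(0.0, 1.0, n_kept) * kernel.rate_sigma * scale
        if excess is not None:
            mutated = cell_exc > _EXCESS_EPS
            cell_exc = np.where(mutated, cell_exc * np.exp(noise_shift), cell_exc)
            floor = minimal_variance(np.exp(cell_mus), floor_params)
            cell_sigma2 = floor + cell_exc
        else:
            with np.errstate(divide="ignore"):
                cell_sigma2 = np.exp(np.log(cell_sigma2) + noise_shift)

        # --- collapse identical phenotypes back to a genotype table
        stacked = np.column_stack([cell_mus, cell_sigma2])
        uniq, counts_new = np.unique(stacked, axis=0, return_counts=True)
        mus, sigma2s, counts = uniq[:, 0], uniq[:, 1], counts_new
        if excess is not None:
            floor = minimal_variance(np.exp(mus), floor_params)
            excess = np.clip(sigma2s - floor, 0.0, None)

        populations.append(Population(mus.copy(), sigma2s.copy(), counts.copy()))
        row = _summary_row(rnd, mus, sigma2s, counts.astype(float), gate, floor_params, excess)
        row["selected_fraction"] = n_kept / cells_sampled
        rows.append(row)

    summary = pd.DataFrame(rows)
    # expected_fraction must describe the pool each sort drew from, i.e. the
    # previous round's population under this round's gate.
    pre_sel = [
        float(
            np.sum(
                (populations[i].counts / populations[i].total)
                * genotype_fitness(populations[i].mus, populations[i].sigma2s, gates[i])
            )
        )
        for i in range(len(gates))
    ]
    summary.loc[0, "expected_fraction"] = np.nan
    summary.loc[1:, "expected_fraction"] = pre_sel
    return EvolutionTrajectory(populations, summary)
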