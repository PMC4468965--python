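"""Minimal-variance (noise floor) model for promoter expression noise.

Expression noise is defined as the variance of log-fluorescence across
genetically identical cells.  Because every reporter is subject to intrinsic
(burst-like) fluctuations and to extrinsic fluctuations of the global
transcription/translation/dilution rates, the variance of log-expression has
a strict lower bound as a function of the mean.  Writing ``<n_meas>`` for the
mean measured fluorescence (in GFP-molecule units, including a background
component ``n_bg``), the floor is

    var(log n_meas) = sigma_ab2 * (1 - n_bg/<n_meas>)**2
                      + (beta/<n_meas>) * (1 - n_bg/<n_meas>)

where ``beta`` is a renormalized burst size (the intrinsic component, which
decays with mean expression) and ``sigma_ab2`` is the relative variance of
the product of transcription, translation and decay rates across cells (the
extrinsic asymptote).  A promoter's *excess noise* is its measured variance
of log-fluorescence above this fitted floor at its mean; unlike raw variance,
excess noise is comparable across promoters with different means.

Natural logarithms are used throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "NoiseFloorParams",
    "PromoterRecord",
    "FlowSample",
    "FloorFitError",
    "minimal_variance",
    "fit_noise_floor",
    "excess_noise",
    "excess_noise_table",
    "estimate_log_stats",
    "records_from_samples",
    "read_promoter_table",
    "write_promoter_table",
    "GFP_MOLECULES_PER_FACS_UNIT_LOG",
]

#: Optional shift from raw FACS log-intensity to log GFP-molecule units
#: (GFP molecules per cell = 2.88 * mean FACS intensity, i.e. y = x + 1.06).
GFP_MOLECULES_PER_FACS_UNIT_LOG = float(np.log(2.88))


class FloorFitError(ValueError):
    """Raised when the promoter set cannot constrain the noise floor."""


@dataclass(frozen=True)
class NoiseFloorParams:
    """Parameters of the minimal-variance curve.

    Attributes
    ----------
    sigma_ab2:
        Relative variance of the product of transcription/translation/decay
        rates across cells (dimensionless extrinsic asymptote).
    beta:
        Renormalized burst size, in GFP-molecule units.
    n_bg:
        Background fluorescence in GFP-molecule units.
    """

    sigma_ab2: float
    beta: float
    n_bg: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_ab2 < 0:
            raise ValueError(f"sigma_ab2 must be >= 0, got {self.sigma_ab2}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.n_bg < 0:
            raise ValueError(f"n_bg must be >= 0, got {self.n_bg}")

    @property
    def burst_size(self) -> float:
        """Simple-model burst size ``b`` from ``var(n) = (b+1)<n>``.

        In the unrenormalized case (no extrinsic rate fluctuations) the
        variance is ``var(n) = beta*<n>`` with ``beta = b + 1``.
        """
        return self.beta - 1.0


@dataclass
class PromoterRecord:
    """Mean/variance of log-expression of one promoter.

    ``excess_noise`` is filled in after the floor has been fitted and may be
    slightly negative for promoters falling below the fitted curve (retained
    unclipped by default to preserve fit-error information).
    """

    promoter_id: str
    mean_log: float
    var_log: float
    n_cells: int = 1
    excess_noise: float | None = None

    def __post_init__(self) -> None:
        if self.var_log < 0:
            raise ValueError(f"var_log must be >= 0, got {self.var_log}")
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")


@dataclass
class FlowSample:
    """Per-cell log-fluorescence values for one promoter."""

    promoter_id: str
    log_values: np.ndarray

    def __post_init__(self) -> None:
        self.log_values = np.asarray(self.log_values, dtype=float)
        if self.log_values.size < 2:
            raise ValueError("a FlowSample needs at least 2 cells")


def minimal_variance(mean_n, params: NoiseFloorParams):
    """Theoretical minimal variance of log-expression at linear-scale mean.

    Parameters
    ----------
    mean_n:
        Mean measured fluorescence ``<n_meas>`` on the linear scale (strictly
        above the background ``params.n_bg``).  Scalar or array.
    params:
        Floor parameters.

    Returns
    -------
    Non-negative variance of log-fluorescence; decreasing in ``mean_n`` far
    above background with asymptote ``params.sigma_ab2``.
    """
    mean_n = np.asarray(mean_n, dtype=float)
    if np.any(mean_n <= params.n_bg):
        raise ValueError(
            "mean_n <= n_bg: expression indistinguishable from background "
            f"(mean_n={mean_n}, n_bg={params.n_bg})"
        )
    above = 1.0 - params.n_bg / mean_n
    out = params.sigma_ab2 * above**2 + (params.beta / mean_n) * above
    return out if out.ndim else float(out)


def excess_noise(record: PromoterRecord, params: NoiseFloorParams, clip: bool = False) -> float:
    """Excess noise of one promoter: ``var_log`` minus the floor at its mean.

    The record's ``mean_log`` is converted to the linear scale as
    ``exp(mean_log)``.  With ``clip=True`` negative values (promoters below
    the fitted floor) are clipped to 0.
    """
    floor = minimal_variance(np.exp(record.mean_log), params)
    excess = record.var_log - floor
    if clip:
        excess = max(excess, 0.0)
    return float(excess)


def excess_noise_table(
    records: Iterable[PromoterRecord], params: NoiseFloorParams, clip: bool = False
) -> pd.DataFrame:
    """Tabulate floor variance and excess noise for a batch of records.

    Mutates each record's ``excess_noise`` field (unclipped) and returns a
    tidy frame with columns ``promoter_id, mean_log, var_log, n_cells,
    floor_variance, excess_noise``.
    """
    rows = []
    for rec in records:
        floor = float(minimal_variance(np.exp(rec.mean_log), params))
        rec.excess_noise = rec.var_log - floor
        value = max(rec.excess_noise, 0.0) if clip else rec.excess_noise
        rows.append(
            {
                "promoter_id": rec.promoter_id,
                "mean_log": rec.mean_log,
                "var_log": rec.var_log,
                "n_cells": rec.n_cells,
                "floor_variance": floor,
                "excess_noise": value,
            }
        )
    return pd.DataFrame(rows)


def _envelope_points(
    mean_log: np.ndarray, var_log: np.ndarray, n_bins: int, quantile: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin lower-envelope points of the mean/variance cloud.

    Promoters are split into equal-count bins of ``mean_log``; within each
    bin the promoter at the ``quantile``-th percentile of ``var_log`` is the
    envelope representative (its own mean is used, avoiding binning bias).
    """
    order = np.argsort(mean_log)
    xs, ys = [], []
    for chunk in np.array_split(order, n_bins):
        if chunk.size == 0:
            continue
        v = var_log[chunk]
        k = min(int(np.floor(quantile / 100.0 * chunk.size)), chunk.size - 1)
        idx = chunk[np.argsort(v, kind="stable")[k]]
        xs.append(mean_log[idx])
        ys.append(var_log[idx])
    return np.asarray(xs), np.asarray(ys)


def fit_noise_floor(
    records: Sequence[PromoterRecord],
    n_bins: int = 20,
    envelope_quantile: float = 5.0,
    n_bg: float | None = None,
    min_promoters: int = 20,
    min_decades: float = 1.0,
) -> NoiseFloorParams:
    """Fit the minimal-variance curve to the lower envelope of a population.

    Parameters
    ----------
    records:
        At least ``min_promoters`` promoters spanning at least
        ``min_decades`` decades of mean expression.
    n_bins, envelope_quantile:
        The envelope is the ``envelope_quantile``-th percentile of
        ``var_log`` within each of ``n_bins`` equal-count bins of
        ``mean_log``; the closed form is least-squares fitted to those
        points.
    n_bg:
        Background fluorescence; fixed at this value when given (e.g. from
        unexpressed controls), co-fitted when ``None``.

    Returns
    -------
    NoiseFloorParams
        On synthetic populations generated on the exact floor plus
        non-negative excess, recovers the generating ``(sigma_ab2, beta)``.
    """
    records = list(records)
    if len(records) < min_promoters:
        raise FloorFitError(
            f"need >= {min_promoters} promoters to fit the floor, got {len(records)}"
        )
    mean_log = np.array([r.mean_log for r in records], dtype=float)
    var_log = np.array([r.var_log for r in records], dtype=float)
    span_decades = (mean_log.max() - mean_log.min()) / np.log(10.0)
    if span_decades < min_decades:
        raise FloorFitError(
            "insufficient dynamic range to constrain the floor: promoters span "
            f"{span_decades:.2f} decades of mean expression (need >= {min_decades})"
        )

    x_log, y = _envelope_points(mean_log, var_log, n_bins, envelope_quantile)
    x = np.exp(x_log)

    # Rough start from the far-from-background regime, where the curve is
    # linear in 1/x: var ~ sigma_ab2 + beta/x.
    slope, intercept = np.polyfit(1.0 / x, y, 1)
    p0_sigma = float(np.clip(intercept, 1e-6, None))
    p0_beta = float(np.clip(slope, 1e-3, None))

    if n_bg is not None:
        if np.any(x <= n_bg):
            raise FloorFitError(
                "envelope contains promoters at or below the fixed background"
            )

        def model(xx, sigma_ab2, beta):
            return minimal_variance(xx, NoiseFloorParams(sigma_ab2, beta, n_bg))

        popt, _ = optimize.curve_fit(
            model, x, y, p0=[p0_sigma, p0_beta],
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000,
        )
        return NoiseFloorParams(float(popt[0]), float(popt[1]), float(n_bg))

    def model_bg(xx, sigma_ab2, beta, bg):
        return minimal_variance(xx, NoiseFloorParams(sigma_ab2, beta, bg))

    bg_hi = 0.99 * float(x.min())
    popt, _ = optimize.curve_fit(
        model_bg, x, y, p0=[p0_sigma, p0_beta, 0.5 * bg_hi],
        bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, bg_hi]), maxfev=50000,
    )
    return NoiseFloorParams(float(popt[0]), float(popt[1]), float(popt[2]))


def _trimmed_stats(values: np.ndarray, trim: float) -> tuple[float, float]:
    """Symmetric-trim mean/variance with truncated-normal bias correction."""
    v = np.sort(values)
    k = int(np.floor(trim * v.size))
    if k > 0:
        v = v[k:-k]
    mean = float(v.mean())
    var = float(v.var(ddof=1)) if v.size > 1 else 0.0
    if k > 0 and var > 0:
        # variance of a normal truncated at +-z_alpha, alpha = trim per tail
        alpha = trim
        z = stats.norm.ppf(1.0 - alpha)
        correction = 1.0 - 2.0 * z * stats.norm.pdf(z) / (1.0 - 2.0 * alpha)
        var /= correction
    return mean, var


def _clipped_stats(values: np.ndarray, z: float = 4.0) -> tuple[float, float]:
    """Sigma-clipped moments: median/MAD pilot, then clip beyond z robust SDs.

    The MAD pilot scale is immune to small contaminated fractions, so gross
    outliers are excluded wholesale; the retained Gaussian core loses only
    the tail mass beyond z (bias-corrected, negligible at z = 4).
    """
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    if mad == 0.0:
        return med, float(values.var(ddof=1))
    scale = 1.4826 * mad  # consistent Gaussian SD
    core = values[np.abs(values - med) <= z * scale]
    mean = float(core.mean())
    var = float(core.var(ddof=1)) if core.size > 1 else 0.0
    tail = stats.norm.sf(z)
    correction = 1.0 - 2.0 * z * stats.norm.pdf(z) / (1.0 - 2.0 * tail)
    return mean, var / correction


def estimate_log_stats(
    sample: FlowSample | np.ndarray,
    outlier_fraction_prior: float = 0.01,
    method: str = "em",
    max_iter: int = 200,
    tol: float = 1e-12,
) -> tuple[float, float]:
    """Outlier-robust mean and variance of log-fluorescence.

    The default estimator fits a two-component mixture by
    expectation-maximization: a Gaussian signal component plus a broad
    uniform outlier component spanning the observed range.  The returned
    moments are those of the Gaussian component, so a small fraction of
    gross outliers (debris, doublets) barely moves them.  ``method="clipped"``
    selects a non-iterative fallback: median/MAD pilot scale, moments of the
    values within 4 robust SDs of the median (bias-corrected); gross
    one-sided contamination is excluded wholesale.

    Returns
    -------
    (mean_log, var_log)
    """
    values = sample.log_values if isinstance(sample, FlowSample) else np.asarray(sample, float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("need at least 2 finite values to estimate mean and variance")
    if np.ptp(values) == 0.0:
        return float(values[0]), 0.0

    if method == "clipped":
        return _clipped_stats(values)
    if method != "em":
        raise ValueError(f"unknown method {method!r}")

    # init from a modest trim so gross outliers do not poison the start
    m, v = _trimmed_stats(values, 0.01)
    v = max(v, 1e-12)
    pi = float(np.clip(outlier_fraction_prior, 1e-6, 0.5))
    span = np.ptp(values)
    lo, hi = values.min() - 0.5 * span, values.max() + 0.5 * span
    unif = 1.0 / (hi - lo)

    for _ in range(max_iter):
        norm_pdf = np.exp(-0.5 * (values - m) ** 2 / v) / np.sqrt(2 * np.pi * v)
        num_out = pi * unif
        resp_out = num_out / (num_out + (1.0 - pi) * norm_pdf)
        w = 1.0 - resp_out  # signal responsibility
        wsum = w.sum()
        m_new = float((w * values).sum() / wsum)
        v_new = float((w * (values - m_new) ** 2).sum() / wsum)
        v_new = max(v_new, 1e-15)
        pi_new = float(np.clip(resp_out.mean(), 1e-9, 0.5))
        if abs(m_new - m) < tol and abs(v_new - v) < tol:
            m, v, pi = m_new, v_new, pi_new
            break
        m, v, pi = m_new, v_new, pi_new
    return m, v


def records_from_samples(
    samples: Iterable[FlowSample],
    outlier_fraction_prior: float = 0.01,
    method: str = "em",
    to_gfp_units: bool = False,
) -> list[PromoterRecord]:
    """Estimate a PromoterRecord from each FlowSample.

    ``to_gfp_units`` shifts the mean by log(2.88) to express it in GFP
    molecules per cell rather than raw FACS intensity (off by default).
    """
    out = []
    for s in samples:
        m, v = estimate_log_stats(s, outlier_fraction_prior, method=method)
        if to_gfp_units:
            m += GFP_MOLECULES_PER_FACS_UNIT_LOG
        out.append(PromoterRecord(s.promoter_id, m, v, n_cells=int(s.log_values.size)))
    return out


def read_promoter_table(path) -> list[PromoterRecord]:
    """Read a TSV with columns promoter_id, mean_log, var_log, n_cells."""
    df = pd.read_csv(path, sep="\t")
    recs = []
    for row in df.itertuples(index=False):
        recs.append(
            PromoterRecord(
                str(row.promoter_id),
                float(row.mean_log),
                float(row.var_log),
                int(getattr(row, "n_cells", 1)),
                excess_noise=float(row.excess_noise) if hasattr(row, "excess_noise") else None,
            )
        )
    return recs


def write_promoter_table(records: Iterable[PromoterRecord], path) -> None:
    rows = [
        {
            "promoter_id": r.promoter_id,
            "mean_log": r.mean_log,
            "var_log": r.var_log,
            "n_cells": r.n_cells,
            "excess_noise": r.excess_noise,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
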