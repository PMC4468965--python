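"""Descriptive associations of excess noise with plasticity and regulation.

Reproduces the cutoff-indexed running-mean analyses (mean expression
plasticity, and mean number of regulatory inputs, of all promoters with
excess noise above a sweeping cutoff), the high-noise enrichment contrast
between promoter groups (hypergeometric test), and per-group cumulative
distributions of excess noise.

Expression plasticity of a gene is the mean of its squared log fold-changes
across conditions (nominally 240 genexpdb experiments); the number of
regulatory inputs of a promoter is the average count of known regulating
transcription factors over the genes of its downstream operon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PlasticityTable",
    "PromoterAnnotation",
    "running_mean_by_cutoff",
    "plasticity_from_logfc",
    "count_regulatory_inputs",
    "threshold_enrichment",
    "cumulative_excess_distributions",
]


@dataclass
class PlasticityTable:
    """Per-gene expression plasticity: mean of squared log fold-changes."""

    table: pd.DataFrame  # columns: gene_id, plasticity, n_conditions


@dataclass
class PromoterAnnotation:
    """Operon-averaged regulatory-input count of one promoter."""

    promoter_id: str
    downstream_genes: list[str]
    n_inputs: float


def running_mean_by_cutoff(
    excess: np.ndarray,
    values: np.ndarray,
    cutoffs: Sequence[float] | None = None,
    inclusive: bool = True,
) -> pd.DataFrame:
    """Mean and SE of ``values`` over promoters with excess above each cutoff.

    ``cutoffs`` defaults to the sorted unique excess values; with the default
    ``inclusive=True`` the selection is ``excess >= cutoff`` so the minimal
    cutoff reproduces the grand mean (``inclusive=False`` uses the strict
    ``excess > cutoff``).  Cutoffs selecting no promoters are omitted with a
    logged note.  SE is sample SD / sqrt(n) (NaN for n = 1).
    """
    excess = np.asarray(excess, float)
    values = np.asarray(values, float)
    if excess.shape != values.shape:
        raise ValueError("excess and values must align")
    if cutoffs is None:
        cutoffs = np.unique(excess)
    rows = []
    for cut in cutoffs:
        mask = excess >= cut if inclusive else excess > cut
        n = int(mask.sum())
        if n == 0:
            logger.info("cutoff %g selects no promoters; omitted", cut)
            continue
        sel = values[mask]
        sd = float(sel.std(ddof=1)) if n > 1 else np.nan
        rows.append(
            {"cutoff": float(cut), "mean": float(sel.mean()), "se": sd / np.sqrt(n), "n": n}
        )
    return pd.DataFrame(rows)


def plasticity_from_logfc(logfc: pd.DataFrame) -> PlasticityTable:
    """Per-gene plasticity from a genes x conditions log fold-change matrix.

    ``logfc`` is indexed by gene_id with one column per condition; missing
    conditions (NaN) are excluded from the mean with the used count
    reported.  Genes with no finite conditions are excluded and logged.
    """
    sq = logfc.astype(float) ** 2
    n_cond = sq.notna().sum(axis=1)
    dropped = n_cond[n_cond == 0].index.tolist()
    if dropped:
        logger.info("excluding %d gene(s) with no conditions: %s", len(dropped), dropped[:5])
    keep = n_cond > 0
    out = pd.DataFrame(
        {
            "gene_id": sq.index[keep],
            "plasticity": sq.loc[keep].mean(axis=1, skipna=True).to_numpy(),
            "n_conditions": n_cond[keep].to_numpy(),
        }
    ).reset_index(drop=True)
    return PlasticityTable(out)


def count_regulatory_inputs(
    promoter_map: pd.DataFrame,
    operon_map: pd.DataFrame,
    interactions: pd.DataFrame,
) -> list[PromoterAnnotation]:
    """Operon-averaged regulatory-input counts per promoter.

    Parameters
    ----------
    promoter_map:
        Columns ``promoter_id, gene_id`` mapping each promoter to its first
        downstream gene.  Promoters whose gene is missing from the operon
        map are excluded with a logged note.
    operon_map:
        Columns ``gene_id, operon_id``: operon membership.
    interactions:
        Columns ``regulator_id, gene_id``; duplicate (regulator, gene) rows
        are collapsed before counting.

    Returns
    -------
    One :class:`PromoterAnnotation` per mappable promoter; ``n_inputs`` is
    the mean TF count over all genes of the downstream operon (genes with
    no known regulators count 0).
    """
    inter = interactions[["regulator_id", "gene_id"]].drop_duplicates()
    inputs_per_gene = inter.groupby("gene_id").size()
    gene_to_operon = dict(zip(operon_map["gene_id"], operon_map["operon_id"]))
    operon_genes = operon_map.groupby("operon_id")["gene_id"].apply(list).to_dict()

    out: list[PromoterAnnotation] = []
    n_unmapped = 0
    for prom, gene in promoter_map[["promoter_id", "gene_id"]].itertuples(index=False):
        if gene not in gene_to_operon:
            n_unmapped += 1
            logger.info("promoter %s: downstream gene %s not in operon map", prom, gene)
            continue
        genes = operon_genes[gene_to_operon[gene]]
        counts = [float(inputs_per_gene.get(g, 0)) for g in genes]
        out.append(PromoterAnnotation(str(prom), [str(g) for g in genes], float(np.mean(counts))))
    if n_unmapped:
        logger.info("excluded %d promoter(s) without operon mapping", n_unmapped)
    return out


def threshold_enrichment(
    excess_a: np.ndarray, excess_b: np.ndarray, threshold: float
) -> tuple[float, float, float]:
    """Fraction of each group above a noise threshold plus enrichment p-value.

    Tests one-sided enrichment of high-excess promoters in group B relative
    to group A (e.g. native vs synthetic promoters at threshold 0.05) with
    an exact hypergeometric tail on the pooled 2x2 table.

    Returns ``(fraction_a, fraction_b, p_value)``.
    """
    a = np.asarray(excess_a, float)
    b = np.asarray(excess_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    ka, kb = int((a > threshold).sum()), int((b > threshold).sum())
    n_tot, k_tot = a.size + b.size, ka + kb
    # P[X >= kb] for X ~ Hypergeom(N=n_tot, K=k_tot, n=|b|)
    p = float(stats.hypergeom.sf(kb - 1, n_tot, k_tot, b.size))
    return ka / a.size, kb / b.size, p


def cumulative_excess_distributions(
    groups: Mapping[str, np.ndarray]
) -> tuple[pd.DataFrame, dict[tuple[str, str], float]]:
    """Empirical CDFs of excess noise per group on a shared grid.

    Returns a tidy frame with columns ``group, x, cdf`` (right-continuous
    step CDFs evaluated on the sorted union of all values) and the maximum
    CDF gap ``max_x |F_a - F_b|`` for every group pair, a summary of
    stochastic dominance.
    """
    if not groups:
        raise ValueError("need at least one group")
    arrays = {k: np.sort(np.asarray(v, float)) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size == 0:
            raise ValueError(f"group {k!r} is empty")
    grid = np.unique(np.concatenate(list(arrays.values())))
    frames = []
    cdfs = {}
    for k, v in arrays.items():
        cdf = np.searchsorted(v, grid, side="right") / v.size
        cdfs[k] = cdf
        frames.append(pd.DataFrame({"group": k, "x": grid, "cdf": cdf}))
    keys = list(arrays)
    gaps = {
        (ka, kb): float(np.max(np.abs(cdfs[ka] - cdfs[kb])))
        for i, ka in enumerate(keys)
        for kb in keys[i + 1:]
    }
    return pd.concat(frames, ignore_index=True), gaps
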