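"""Pairwise Vst divergence scanning over the copy-number matrix.

Vst is the copy-number analogue of Fst:

    Vst = (Vt - Vs) / Vt

with ``Vt`` the variance of copy number over the two populations pooled and
``Vs`` the population-size-weighted mean of the within-population
variances, Vs = (n1*V1 + n2*V2) / (n1 + n2).  All variances use the sample
count as divisor (population variance), the classical convention for this
statistic.  A region with ``Vt = 0`` is copy-number invariant across the
pooled samples and is assigned Vst = 0 so that ranking stays total;
negative Vst values (within-population variance exceeding the pooled one)
are retained.

Outliers are called either as the top fraction of the ranking (upper-5%
scan) or as the records strictly above a percentile of the Vst
distribution (e.g. the 98th percentile used for gene listing); percentiles
use linear interpolation between order statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .annotation_overlap import ContextCall
from .genotyping import CnMatrix
from .io_formats import ConfigError, DataError, PopulationMap

__all__ = [
    "VstRecord",
    "OutlierPolicy",
    "vst_pairwise",
    "mean_vst",
    "call_outliers",
    "outlier_genes",
    "write_vst_table",
]

logger = logging.getLogger(__name__)


@dataclass
class VstRecord:
    cnvr_id: str
    pop_pair: tuple[str, str]  # lexicographically ordered
    vt: float
    vs: float
    vst: float
    percentile_rank: float

    def __post_init__(self) -> None:
        if self.vt < 0 or self.vs < 0:
            raise ValueError("variances cannot be negative")
        if self.vst > 1 + 1e-12:
            raise ValueError("vst cannot exceed 1")


@dataclass(frozen=True)
class OutlierPolicy:
    """Upper-tail outlier definition for the Vst ranking."""

    mode: str = "top_fraction"  # or "percentile_threshold"
    top_fraction: float = 0.05
    percentile: float = 98.0

    def __post_init__(self) -> None:
        if self.mode not in ("top_fraction", "percentile_threshold"):
            raise ConfigError(f"unknown outlier mode {self.mode!r}")
        if not 0.0 < self.top_fraction < 1.0:
            raise ConfigError("top_fraction must be in (0, 1)")
        if not 0.0 < self.percentile < 100.0:
            raise ConfigError("percentile must be in (0, 100)")


def _pop_variance(x: np.ndarray) -> np.ndarray:
    """Row-wise variance with divisor n (ddof=0)."""
    return np.asarray(x, dtype=float).var(axis=1, ddof=0)


def vst_pairwise(
    matrix: CnMatrix,
    pops: PopulationMap,
    pair: tuple[str, str],
    variance_ddof: int = 0,
) -> list[VstRecord]:
    """Compute Vst per CNVR for one population pair.

    Masked (imputed) cells enter at their imputed value; their count is
    logged so downstream interpretation can weigh them.  Both populations
    must have at least two samples present in the matrix.
    """
    a, b = sorted(pair)
    samples_a = [s for s in matrix.sample_ids if pops.assignments.get(s) == a]
    samples_b = [s for s in matrix.sample_ids if pops.assignments.get(s) == b]
    for label, samples in ((a, samples_a), (b, samples_b)):
        if len(samples) < 2:
            raise DataError(
                f"population {label!r} has {len(samples)} sample(s) in the matrix; need >= 2"
            )
    n1, n2 = len(samples_a), len(samples_b)
    n_masked = int(matrix.mask[samples_a + samples_b].to_numpy().sum())
    if n_masked:
        logger.info("vst %s-%s: %d imputed cell(s) included", a, b, n_masked)

    xa = matrix.values[samples_a].to_numpy(dtype=float)
    xb = matrix.values[samples_b].to_numpy(dtype=float)
    pooled = np.concatenate([xa, xb], axis=1)

    def var(x: np.ndarray) -> np.ndarray:
        return x.var(axis=1, ddof=variance_ddof)

    vt = var(pooled)
    v1 = var(xa)
    v2 = var(xb)
    vs = (n1 * v1 + n2 * v2) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        vst = np.where(vt > 0, (vt - vs) / np.where(vt > 0, vt, 1.0), 0.0)
    pct = rankdata(vst, method="average") / len(vst) * 100.0

    return [
        VstRecord(
            cnvr_id=cnvr_id,
            pop_pair=(a, b),
            vt=float(vt[i]),
            vs=float(vs[i]),
            vst=float(vst[i]),
            percentile_rank=float(pct[i]),
        )
        for i, cnvr_id in enumerate(matrix.cnvr_ids)
    ]


def mean_vst(records: Sequence[VstRecord]) -> float:
    """Arithmetic mean Vst over all regions of one pair (negatives included)."""
    if not records:
        raise DataError("mean_vst of an empty record list")
    return float(np.mean([r.vst for r in records]))


def call_outliers(
    records: Sequence[VstRecord],
    policy: OutlierPolicy = OutlierPolicy(),
) -> tuple[list[str], float]:
    """Return (outlier cnvr_ids, threshold) under the given policy.

    top_fraction: sort descending and take ceil(fraction * N) records; the
    threshold is the smallest included Vst (ties beyond the count are cut
    deterministically by cnvr_id).  percentile_threshold: the threshold is
    the requested percentile of the Vst distribution (linear interpolation)
    and outliers are the records strictly above it.
    """
    if not records:
        raise DataError("call_outliers on an empty record list")
    if policy.mode == "top_fraction":
        k = math.ceil(policy.top_fraction * len(records))
        ranked = sorted(records, key=lambda r: (-r.vst, r.cnvr_id))
        chosen = ranked[:k]
        return [r.cnvr_id for r in chosen], float(chosen[-1].vst)
    threshold = float(np.percentile([r.vst for r in records], policy.percentile))
    chosen = [r for r in records if r.vst > threshold]
    return [r.cnvr_id for r in chosen], threshold


def outlier_genes(
    outlier_ids: Sequence[str],
    contexts: Sequence[ContextCall],
) -> list[str]:
    """Deduplicated, sorted union of nearby genes over outlier CNVRs."""
    by_id = {c.cnvr_id: c for c in contexts}
    genes: set[str] = set()
    for cnvr_id in outlier_ids:
        ctx = by_id.get(cnvr_id)
        if ctx is not None:
            genes |= ctx.genes_within_flank
    return sorted(genes)


def write_vst_table(
    records: Sequence[VstRecord],
    path,
    cnvr_coords: Mapping[str, tuple[str, int, int]] | None = None,
) -> None:
    """Write records as a Manhattan-plot-ready TSV.

    ``cnvr_coords`` (cnvr_id -> (chrom, start, end)) adds chromosome and
    midpoint columns; without it those columns are empty.
    """
    with open(path, "w") as fh:
        fh.write("cnvr_id\tchrom\tmidpoint\tpair\tvt\tvs\tvst\tpercentile_rank\n")
        for r in records:
            chrom, mid = "", ""
            if cnvr_coords and r.cnvr_id in cnvr_coords:
                c, s, e = cnvr_coords[r.cnvr_id]
                chrom, mid = c, str((s + e) // 2)
            pair = f"{r.pop_pair[0]}-{r.pop_pair[1]}"
            fh.write(
                f"{r.cnvr_id}\t{chrom}\t{mid}\t{pair}\t{r.vt!r}\t{r.vs!r}\t{r.vst!r}\t{r.percentile_rank!r}\n"
            )
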