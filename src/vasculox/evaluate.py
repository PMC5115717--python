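"""Comparison statistics for computed oxygen fields.

Covers the quantities used to judge the computation schemes against each
other: hypoxic fractions at 0.01 / 1 / 5 mmHg thresholds, vascular
fraction, field mean and population SD, 1 mmHg-resolution normalized and
cumulative pO₂ histograms, the RMSD between two distributions (on the
cumulative curves, so 0 means identical and ≈1 means total separation),
a two-sample Kolmogorov–Smirnov test with the large-sample critical
value c(α)·√((n₁+n₂)/(n₁·n₂)), and the Pearson correlation matrix of
per-sample properties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "DistributionSummary",
    "KsResult",
    "hypoxic_fraction",
    "vascular_fraction",
    "field_stats",
    "distribution",
    "rmsd",
    "ks_two_sample",
    "correlation_matrix",
    "KS_CRITICAL",
]

#: large-sample critical coefficients c(α) for the two-sample KS test
KS_CRITICAL = {0.10: 1.22, 0.05: 1.36, 0.025: 1.48, 0.01: 1.63,
               0.005: 1.73, 0.001: 1.95}


def _values(field) -> np.ndarray:
    """Accept an OxygenField, VoxelGrid or bare array; return a flat view."""
    v = getattr(field, "values", field)
    return np.asarray(v).ravel()


def hypoxic_fraction(field, threshold_mmhg: float) -> float:
    """Fraction of voxels with pO₂ strictly below the threshold."""
    v = _values(field)
    if v.size == 0:
        raise ValueError("empty field")
    return float(np.count_nonzero(v < threshold_mmhg) / v.size)


def vascular_fraction(vessel_mask, crop: int = 0) -> float:
    """Nonzero-voxel fraction of a vessel mask, optionally after removing
    ``crop`` voxels from every face (pad removal)."""
    m = np.asarray(getattr(vessel_mask, "mask", vessel_mask))
    if crop:
        m = m[(slice(crop, -crop),) * 3]
    if m.size == 0:
        raise ValueError("empty mask")
    return float(np.count_nonzero(m) / m.size)


def field_stats(field) -> tuple[float, float]:
    """(arithmetic mean, population SD) over all voxels."""
    v = _values(field)
    return float(v.mean()), float(v.std(ddof=0))


@dataclass
class DistributionSummary:
    """Normalized pO₂ histogram plus the headline scalars.

    ``histogram`` sums to 1; ``cumulative`` is its running sum (last value
    1). Bin i covers [i·bin_width, (i+1)·bin_width).
    """

    bin_width: float
    bin_edges: np.ndarray
    histogram: np.ndarray
    cumulative: np.ndarray
    hf_001: float
    hf_1: float
    hf_5: float
    vascular_fraction: float | None
    mean_po2: float
    sd_po2: float

    def as_dict(self) -> dict:
        return {
            "HF_0.01": self.hf_001, "HF_1": self.hf_1, "HF_5": self.hf_5,
            "VF": self.vascular_fraction,
            "mean_pO2": self.mean_po2, "sd_pO2": self.sd_po2,
        }


def distribution(field, bin_width: float = 1.0,
                 vessel_mask=None, min_bins: int = 101) -> DistributionSummary:
    """Histogram a field at the given resolution (default 1 mmHg) on
    [0, max(100, field max) + bin), with hypoxic fractions computed from the
    raw voxel values (strict <)."""
    v = _values(field)
    if v.size == 0:
        raise ValueError("empty field")
    n_bins = max(min_bins, int(np.ceil((v.max() + bin_width * 1e-9) / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    hist, _ = np.histogram(v, bins=edges)
    hist = hist / v.size
    vf = None if vessel_mask is None else vascular_fraction(vessel_mask)
    mean, sd = field_stats(v)
    return DistributionSummary(
        bin_width=bin_width, bin_edges=edges,
        histogram=hist, cumulative=np.cumsum(hist),
        hf_001=hypoxic_fraction(v, 0.01),
        hf_1=hypoxic_fraction(v, 1.0),
        hf_5=hypoxic_fraction(v, 5.0),
        vascular_fraction=vf, mean_po2=mean, sd_po2=sd,
    )


def rmsd(dist_a: DistributionSummary, dist_b: DistributionSummary,
         on: str = "cumulative") -> float:
    """Root mean square deviation between two distributions.

    The default compares the cumulative normalized distributions — the
    convention under which identical inputs give 0 and two single-bin
    distributions at opposite ends of the range give ≈1. ``on="density"``
    compares the normalized histograms instead. Both distributions must
    share the bin width; the shorter cumulative curve is extended with 1s
    (histogram with 0s) to the common length.
    """
    if abs(dist_a.bin_width - dist_b.bin_width) > 1e-12:
        raise ValueError("distributions use different bin widths")
    if on == "cumulative":
        a, b = dist_a.cumulative, dist_b.cumulative
        fill = 1.0
    elif on == "density":
        a, b = dist_a.histogram, dist_b.histogram
        fill = 0.0
    else:
        raise ValueError("on must be 'cumulative' or 'density'")
    n = max(a.size, b.size)
    a = np.pad(a, (0, n - a.size), constant_values=fill)
    b = np.pad(b, (0, n - b.size), constant_values=fill)
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass
class KsResult:
    """Two-sample Kolmogorov–Smirnov decision at the large-sample critical
    value; rejection means the two voxel populations are not draws from a
    common distribution."""

    d_ks: float
    n1: int
    n2: int
    alpha: float
    c_alpha: float
    threshold: float
    reject: bool


def ks_two_sample(values_a, values_b, alpha: float = 0.05,
                  c_alpha: float | None = None) -> KsResult:
    """Exact merged-ECDF sup-distance between two samples and the
    large-sample decision D > c(α)·√((n₁+n₂)/(n₁·n₂)).

    ``c_alpha`` overrides the tabulated coefficient (available α:
    0.10, 0.05, 0.025, 0.01, 0.005, 0.001).
    """
    a = np.sort(np.asarray(values_a).ravel())
    b = np.sort(np.asarray(values_b).ravel())
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if c_alpha is None:
        try:
            c_alpha = KS_CRITICAL[alpha]
        except KeyError:
            raise ValueError(f"no tabulated c(α) for α={alpha}; pass c_alpha")
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    n1, n2 = int(a.size), int(b.size)
    threshold = c_alpha * np.sqrt((n1 + n2) / (n1 * n2))
    return KsResult(d_ks=d, n1=n1, n2=n2, alpha=alpha, c_alpha=c_alpha,
                    threshold=float(threshold), reject=bool(d > threshold))


def correlation_matrix(sample_table) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Pearson r and two-sided p-values for a table of per-sample
    properties (rows = samples, columns = properties; pandas DataFrame or
    2D array, n ≥ 3 rows).

    The diagonal (a property against itself) carries no information and is
    returned as NaN, as are pairs involving a zero-variance column.
    """
    import pandas as pd
    if isinstance(sample_table, pd.DataFrame):
        x = sample_table.to_numpy(dtype=float)
    else:
        x = np.asarray(sample_table, dtype=float)
    n, p = x.shape
    if n < 3:
        raise ValueError("need at least 3 samples for correlation p-values")
    r = np.full((p, p), np.nan)
    pv = np.full((p, p), np.nan)
    for i in range(p):
        for j in range(i + 1, p):
            if x[:, i].std() == 0 or x[:, j].std() == 0:
                continue
            res = sps.pearsonr(x[:, i], x[:, j])
            r[i, j] = r[j, i] = res.statistic
            pv[i, j] = pv[j, i] = res.pvalue
    return r, pv
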