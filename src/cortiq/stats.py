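"""Voxel-wise statistics: tissue summaries, group tests, correlations,
normalized histograms.

Implements the statistical comparison of cortical lesions against
normal-appearing cortex (and WM lesions against normal-appearing WM):
per-tissue mean/SD tables, two-sided two-sample t-tests with Bonferroni
correction, Pearson and Spearman correlations between the quantitative MR
parameters and myelin content, and per-tissue histograms normalized by voxel
count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "Histogram",
    "roi_summaries",
    "group_compare",
    "correlate",
    "normalized_histogram",
]


@dataclass(frozen=True)
class GroupComparison:
    t: float
    p_raw: float
    p_corrected: float
    significant: bool
    n_a: int
    n_b: int
    equal_var: bool

    def as_dict(self) -> dict:
        return {
            "t": self.t,
            "p_raw": self.p_raw,
            "p_corrected": self.p_corrected,
            "significant": bool(self.significant),
            "n_a": self.n_a,
            "n_b": self.n_b,
            "equal_var": self.equal_var,
        }


@dataclass(frozen=True)
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int
    undefined: bool = False

    def as_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "n": self.n,
            "undefined": bool(self.undefined),
        }


@dataclass(frozen=True)
class Histogram:
    """Voxel-count-normalized histogram with explicit overflow bins.

    ``frequencies`` are in-range bin counts / n; ``underflow``/``overflow``
    carry the out-of-range mass, so the three always sum to 1.
    """

    bin_edges: np.ndarray
    frequencies: np.ndarray
    underflow: float
    overflow: float
    n: int

    def total_mass(self) -> float:
        return float(self.frequencies.sum() + self.underflow + self.overflow)


def group_compare(
    values_a: np.ndarray,
    values_b: np.ndarray,
    alpha: float = 0.05,
    n_comparisons: int = 5,
    equal_var: bool = True,
) -> GroupComparison:
    """Two-sided two-sample t-test with Bonferroni correction.

    Defaults to the pooled-variance Student test with a 5-fold correction
    (one comparison per quantitative parameter: T1, T2, M0, MTR, myelin);
    ``equal_var=False`` switches to Welch. Two zero-variance groups with
    equal means yield t = 0, p = 1 by convention; with different means the
    difference is infinitely significant (p = 0).
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 finite values")
    if a.std() == 0.0 and b.std() == 0.0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = np.inf if a.mean() > b.mean() else -np.inf
            p = 0.0
    else:
        t, p = sstats.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(t), float(p)
    p_corr = min(1.0, p * n_comparisons)
    return GroupComparison(
        t=t, p_raw=p, p_corrected=p_corr, significant=p_corr < alpha,
        n_a=int(a.size), n_b=int(b.size), equal_var=equal_var,
    )


def correlate(qvalues: np.ndarray, myelin_values: np.ndarray) -> CorrelationResult:
    """Pearson r and Spearman rho between a qMR parameter and myelin content.

    Spearman uses average ranks for ties. Pairs with non-finite members are
    dropped; zero variance in either variable returns an undefined-flagged
    result (NaN coefficients) rather than raising.
    """
    x = np.asarray(qvalues, dtype=np.float64)
    y = np.asarray(myelin_values, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("paired value arrays must have the same shape")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("at least 3 finite pairs are required")
    if x.std() == 0.0 or y.std() == 0.0:
        return CorrelationResult(np.nan, np.nan, np.nan, np.nan, int(x.size), True)
    pr = sstats.pearsonr(x, y)
    sr = sstats.spearmanr(x, y)
    return CorrelationResult(
        float(pr.statistic), float(pr.pvalue),
        float(sr.statistic), float(sr.pvalue), int(x.size), False,
    )


def normalized_histogram(values: np.ndarray, bin_edges: np.ndarray) -> Histogram:
    """Histogram normalized by the total number of finite values.

    Out-of-range values are not dropped silently: they are counted in the
    underflow/overflow fields so the total mass is always exactly 1.
    """
    edges = np.asarray(bin_edges, dtype=np.float64)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    v = np.asarray(values, dtype=np.float64)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("at least one finite value is required")
    counts, _ = np.histogram(v, bins=edges)
    under = int((v < edges[0]).sum())
    over = int((v > edges[-1]).sum())
    n = v.size
    return Histogram(
        bin_edges=edges,
        frequencies=counts / n,
        underflow=under / n,
        overflow=over / n,
        n=int(n),
    )


def default_bin_edges(values: np.ndarray, n_bins: int = 64) -> np.ndarray:
    """Default histogram support: 64 uniform bins over the pooled 1st-99th
    percentile range (degenerate ranges are widened symmetrically)."""
    v = np.asarray(values, dtype=np.float64)
    v = v[np.isfinite(v)]
    lo, hi = np.percentile(v, [1, 99])
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    return np.linspace(lo, hi, n_bins + 1)


def roi_summaries(
    qmaps: dict[str, np.ndarray],
    roi_masks: dict[str, np.ndarray],
    valid_masks: Optional[dict[str, np.ndarray]] = None,
) -> pd.DataFrame:
    """Mean/SD/voxel-count table per (tissue ROI, parameter).

    ``roi_masks`` must be disjoint and are expected to already incorporate
    the mask hygiene of the analysis (cortical ROIs intersected with the
    eroded cortical mask, banding exclusions removed). ``valid_masks``
    optionally restricts each parameter to its fit-valid voxels. Empty ROIs
    are reported as explicit empty rows (n = 0, NaN moments), single-voxel
    ROIs report SD 0 with an n = 1 flag.
    """
    names = list(roi_masks)
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            if np.any(roi_masks[na] & roi_masks[nb]):
                raise ValueError(f"ROI masks {na!r} and {nb!r} overlap")
    rows = []
    for roi, rmask in roi_masks.items():
        for param, qmap in qmaps.items():
            sel = rmask.copy()
            if valid_masks is not None and param in valid_masks:
                sel &= valid_masks[param]
            vals = np.asarray(qmap)[sel]
            vals = vals[np.isfinite(vals)]
            n = int(vals.size)
            rows.append(
                {
                    "roi": roi,
                    "parameter": param,
                    "mean": float(vals.mean()) if n else np.nan,
                    "sd": float(vals.std(ddof=1)) if n > 1 else (0.0 if n == 1 else np.nan),
                    "n": n,
                }
            )
    return pd.DataFrame(rows)
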