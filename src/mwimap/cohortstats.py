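"""Cohort statistics: atlases, ROI tables, agreement and Z-score maps.

Normative voxel-wise mean/SD atlases are built from aligned healthy
subject maps; individual subjects are compared to them as Z scores,
masked where the atlas coefficient of variation marks the reference as
unreliable. ROI summaries and paired comparisons mirror the reporting
conventions of quantitative myelin imaging studies: metric values stored
as fractions, rendered as percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import QuantMap

__all__ = [
    "AtlasPair",
    "ZScoreMap",
    "BlandAltman",
    "build_atlas",
    "roi_stats",
    "roi_metric_difference",
    "paired_ttest",
    "bland_altman",
    "zscore_map",
    "zscore_histogram",
    "format_roi_table",
]


@dataclass
class AtlasPair:
    """Voxel-wise mean and sample-SD maps over an aligned cohort.

    ``coverage_mask`` marks voxels finite in every subject; the maps are
    NaN outside it.
    """

    mean_map: QuantMap
    sd_map: QuantMap
    n_subjects: int
    coverage_mask: np.ndarray


@dataclass
class ZScoreMap:
    """Subject-vs-atlas Z map with deficiency and exclusion masks."""

    z: QuantMap
    deficient_mask: np.ndarray
    cov_excluded_mask: np.ndarray


@dataclass
class BlandAltman:
    bias: float
    loa_lo: float
    loa_hi: float
    means: np.ndarray
    diffs: np.ndarray


def _as_array(m) -> np.ndarray:
    return m.data if isinstance(m, QuantMap) else np.asarray(m, dtype=float)


def build_atlas(maps) -> AtlasPair:
    """Voxel-wise mean and sample SD (n-1) over aligned subject maps.

    Voxels not finite in every subject are cropped from the atlas
    (coverage rule): mean and SD are NaN there.
    """
    arrs = [_as_array(m) for m in maps]
    if len(arrs) < 2:
        raise ValueError("need at least two subjects to build an atlas")
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("subject maps are not on a common grid")
    stack = np.stack(arrs)
    coverage = np.all(np.isfinite(stack), axis=0)
    mean = np.full(shape, np.nan)
    sd = np.full(shape, np.nan)
    mean[coverage] = stack[:, coverage].mean(axis=0)
    sd[coverage] = stack[:, coverage].std(axis=0, ddof=1)
    return AtlasPair(
        mean_map=QuantMap(mean, "atlas_mean"),
        sd_map=QuantMap(sd, "atlas_sd"),
        n_subjects=len(arrs),
        coverage_mask=coverage,
    )


def roi_stats(map_, rois, roi_groups: dict | None = None) -> pd.DataFrame:
    """Per-ROI mean, SD and voxel count of the finite voxels of a map.

    ``rois`` is an integer label volume; ``roi_groups`` optionally maps ROI
    names to sets of label codes (default: one ROI per nonzero label,
    named by its code). Metric values are fractions; the table reports
    them as percentages (columns mean_pct, sd_pct, n_voxels).
    """
    data = _as_array(map_)
    rois = np.asarray(rois)
    if rois.shape != data.shape:
        raise ValueError("label volume not on the map grid")
    if roi_groups is None:
        roi_groups = {str(code): {int(code)} for code in np.unique(rois) if code != 0}
    rows = []
    for name, codes in roi_groups.items():
        m = np.isin(rois, list(codes)) & np.isfinite(data)
        if not np.any(m):
            continue
        vals = data[m]
        rows.append((name, 100.0 * vals.mean(),
                     100.0 * vals.std(ddof=1) if vals.size > 1 else 0.0,
                     int(vals.size)))
    return pd.DataFrame(
        rows, columns=["roi", "mean_pct", "sd_pct", "n_voxels"]
    ).set_index("roi")


def format_roi_table(table: pd.DataFrame) -> pd.DataFrame:
    """Render a RoiTable with percentages at one decimal, as published."""
    out = table.copy()
    out["mean_pct"] = out["mean_pct"].round(1)
    out["sd_pct"] = out["sd_pct"].round(1)
    return out


def roi_metric_difference(table_a: pd.DataFrame, table_b: pd.DataFrame,
                          roi: str) -> float:
    """Mean metric difference (b - a) for one ROI, in percentage points."""
    if roi not in table_a.index or roi not in table_b.index:
        raise KeyError(f"ROI {roi!r} missing from a table")
    return float(table_b.loc[roi, "mean_pct"] - table_a.loc[roi, "mean_pct"])


def paired_ttest(values_a, values_b) -> tuple:
    """Classical paired two-tailed t test (df = n - 1).

    Zero-variance differences are handled explicitly: identical samples
    give (t=0, p=1); constant nonzero differences give (t=+/-inf, p=0).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    d = b - a
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(b, a)
    return float(t), float(p)


def bland_altman(values_a, values_b) -> BlandAltman:
    """Agreement of paired measurements: bias and 1.96-SD limits.

    diffs = b - a; bias = mean(diffs); limits = bias +/- 1.96 sd(diffs)
    with the sample SD (n-1).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    diffs = b - a
    means = 0.5 * (a + b)
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(bias=bias, loa_lo=bias - 1.96 * sd, loa_hi=bias + 1.96 * sd,
                       means=means, diffs=diffs)


def zscore_map(
    subject,
    atlas: AtlasPair,
    cov_threshold: float = 0.75,
    deficiency_cut: float = -1.96,
) -> ZScoreMap:
    """Z = (subject - atlas mean) / atlas SD, with CoV-based exclusion.

    Voxels where the atlas coefficient of variation (SD/mean) exceeds
    ``cov_threshold`` — including non-positive-mean and zero-SD voxels —
    are excluded (NaN) and flagged in ``cov_excluded_mask``.
    ``deficient_mask`` marks defined voxels with Z <= ``deficiency_cut``.
    """
    x = _as_array(subject)
    mean = atlas.mean_map.data
    sd = atlas.sd_map.data
    if x.shape != mean.shape:
        raise ValueError("subject map not on the atlas grid")
    defined = atlas.coverage_mask & np.isfinite(x)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sd / mean
    unreliable = defined & ((mean <= 0) | (sd == 0) | (cov > cov_threshold))
    keep = defined & ~unreliable
    z = np.full(x.shape, np.nan)
    z[keep] = (x[keep] - mean[keep]) / sd[keep]
    return ZScoreMap(
        z=QuantMap(z, "z"),
        deficient_mask=keep & (np.nan_to_num(z, nan=np.inf) <= deficiency_cut),
        cov_excluded_mask=unreliable,
    )


def zscore_histogram(zmap: ZScoreMap, bin_width: float = 0.25) -> tuple:
    """Histogram of defined Z values on bins of fixed width.

    Returns (bin_edges, counts); counts sum to the number of defined
    voxels. An empty map yields empty arrays.
    """
    vals = zmap.z.values()
    if vals.size == 0:
        return np.array([]), np.array([], dtype=int)
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width
    n = max(int(round((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n + 1)
    counts, _ = np.histogram(vals, bins=edges)
    return edges, counts
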