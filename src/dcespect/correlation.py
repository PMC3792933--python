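"""Voxel-wise correlation between SPECT uptake and DCE-derived parameter maps.

Three summaries per the analysis plan: Spearman rank correlation per dataset,
bidirectional rank-decile tables (median/Q1/Q3 of the companion quantity), and
a pooled linear regression of per-decile medians across datasets.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "build_voxel_table",
    "spearman",
    "decile_summary",
    "decile_indices",
    "pooled_regression",
]

SPECT_COLUMN = "spect_kbq"


def build_voxel_table(spect_map, parameter_maps: dict, analysis_mask,
                      dataset_id) -> pd.DataFrame:
    """One row per in-mask voxel with the SPECT value and every parameter.

    Undefined parameter values are carried as NaN (flags), not dropped; gated
    pharmacokinetic voxels must already hold 0, per the zeroing rule.
    """
    spect = np.asarray(spect_map, dtype=float)
    mask = np.asarray(analysis_mask, dtype=bool)
    for name, pm in parameter_maps.items():
        arr = np.asarray(pm, dtype=float)
        if arr.shape != spect.shape:
            raise ValueError(
                f"grid mismatch for '{name}': {arr.shape} vs {spect.shape}"
            )
    if mask.shape != spect.shape:
        raise ValueError(f"grid mismatch for mask: {mask.shape} vs {spect.shape}")
    ijk = np.argwhere(mask)
    data = {
        "dataset_id": [dataset_id] * len(ijk),
        "i": ijk[:, 0],
        "j": ijk[:, 1],
        "k": ijk[:, 2],
        SPECT_COLUMN: spect[mask],
    }
    for name, pm in parameter_maps.items():
        data[name] = np.asarray(pm, dtype=float)[mask]
    return pd.DataFrame(data)


def spearman(table: pd.DataFrame, parameter: str, against: str = SPECT_COLUMN):
    """Spearman rho (mean ranks for ties) and two-sided t-approximation p.

    Rows where either column is undefined are excluded.
    """
    x = table[parameter].to_numpy(dtype=float)
    y = table[against].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 10:
        raise ValueError(f"need at least 10 defined rows, got {x.size}")
    for name, col in ((parameter, x), (against, y)):
        if np.all(col == col[0]):
            raise ValueError(f"column '{name}' is constant; Spearman undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def decile_indices(values, n_bins: int = 10, mode: str = "rank") -> np.ndarray:
    """Bin index (1..n_bins) per row.

    ``rank`` mode splits the sort order into contiguous bins of near-equal
    count: the first ``n % n_bins`` bins get ``ceil(n/n_bins)`` rows, the rest
    ``floor(n/n_bins)``; ties keep their stable sort order. ``width`` mode
    bins by equal value width instead.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} rows, got {n}")
    out = np.empty(n, dtype=int)
    if mode == "rank":
        order = np.argsort(v, kind="stable")
        base, extra = divmod(n, n_bins)
        sizes = [base + 1] * extra + [base] * (n_bins - extra)
        start = 0
        for b, size in enumerate(sizes, start=1):
            out[order[start:start + size]] = b
            start += size
        return out
    if mode == "width":
        edges = np.linspace(v.min(), v.max(), n_bins + 1)
        out = np.clip(np.digitize(v, edges[1:-1], right=False) + 1, 1, n_bins)
        return out
    raise ValueError(f"unknown decile mode: {mode!r}")


def decile_summary(table: pd.DataFrame, bin_on: str, summarize: str,
                   n_bins: int = 10, mode: str = "rank") -> pd.DataFrame:
    """Rank-decile table: per bin, count and median/Q1/Q3 of ``summarize``.

    Quartiles use linear interpolation. Rows with undefined ``bin_on`` are
    excluded; undefined ``summarize`` values are ignored within each bin.
    """
    sub = table[np.isfinite(table[bin_on].to_numpy(dtype=float))]
    bins = decile_indices(sub[bin_on].to_numpy(dtype=float), n_bins, mode)
    y = sub[summarize].to_numpy(dtype=float)
    rows = []
    for b in range(1, n_bins + 1):
        yb = y[bins == b]
        defined = yb[np.isfinite(yb)]
        if defined.size:
            med, q1, q3 = np.percentile(defined, [50, 25, 75])
        else:
            med = q1 = q3 = np.nan
        rows.append({"bin": b, "n": int(yb.size), "median": med, "q1": q1, "q3": q3})
    out = pd.DataFrame(rows)
    out.attrs["bin_on"] = bin_on
    out.attrs["summarize"] = summarize
    return out


def pooled_regression(tables, parameter: str, bin_on: str = SPECT_COLUMN,
                      n_bins: int = 10, mode: str = "rank",
                      return_details: bool = False):
    """OLS of pooled per-decile medians against the decile index.

    Deciles are assigned per dataset on ``bin_on`` (scales differ between
    subjects); for each decile index the voxels of that decile are pooled
    across datasets and the median of ``parameter`` taken. Regression is the
    pooled median against the index 1..n_bins.

    Returns ``(slope, intercept, r_squared, p)``; with ``return_details`` the
    pooled medians and the per-dataset median envelope are included.
    """
    tables = list(tables)
    if len(tables) < 2:
        raise ValueError("pooled regression needs at least 2 datasets")
    pooled = {b: [] for b in range(1, n_bins + 1)}
    per_dataset = np.full((len(tables), n_bins), np.nan)
    for d, table in enumerate(tables):
        sub = table[np.isfinite(table[bin_on].to_numpy(dtype=float))]
        bins = decile_indices(sub[bin_on].to_numpy(dtype=float), n_bins, mode)
        y = sub[parameter].to_numpy(dtype=float)
        for b in range(1, n_bins + 1):
            yb = y[(bins == b) & np.isfinite(y)]
            pooled[b].append(yb)
            if yb.size:
                per_dataset[d, b - 1] = np.median(yb)
    medians = np.empty(n_bins)
    for b in range(1, n_bins + 1):
        allv = np.concatenate(pooled[b]) if pooled[b] else np.empty(0)
        if allv.size == 0:
            raise ValueError(f"decile {b} has no defined '{parameter}' values")
        medians[b - 1] = np.median(allv)
    x = np.arange(1, n_bins + 1, dtype=float)
    if np.ptp(medians) == 0.0:
        out = (0.0, float(medians[0]), 0.0, 1.0)
    else:
        res = stats.linregress(x, medians)
        out = (float(res.slope), float(res.intercept), float(res.rvalue**2),
               float(res.pvalue))
    if return_details:
        return out + (medians, per_dataset)
    return out
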