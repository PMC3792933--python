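"""Semi-quantitative enhancement-curve features and min-max map normalization.

Six features are computed from the enhancement curve
``e(t) = S(t) - S_baseline`` restricted to post-baseline frames:

* ``smax``     -- maximum enhancement;
* ``ttp``      -- time of the first maximum, relative to the first
                  post-baseline frame (s);
* ``auc``      -- trapezoidal area under the whole enhancement curve;
* ``auc60``    -- area over the first 60 s of the post-baseline window (the
                  last sub-interval is linearly interpolated);
* ``wash_in``  -- slope between the first upward crossings of 10% and 90% of
                  smax (crossing times by linear interpolation);
* ``wash_out`` -- slope between the maximum and the last time point; undefined
                  when the maximum sits on the final frame.

Undefined features are NaN.
"""
from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter1d

__all__ = [
    "FEATURE_NAMES",
    "compute_features",
    "compute_feature_maps",
    "normalize_map",
    "smooth_curves",
]

FEATURE_NAMES = ("smax", "ttp", "auc", "auc60", "wash_in", "wash_out")

AUC60_WINDOW_S = 60.0


def smooth_curves(curves, window: int):
    """Moving-average temporal smoothing (edge-replicated). window<=1 is a no-op."""
    if window <= 1:
        return np.asarray(curves, dtype=float)
    return uniform_filter1d(np.asarray(curves, dtype=float), size=window, axis=-1,
                            mode="nearest")


def _first_upward_crossing(t, e, level):
    """Time of the first upward crossing of ``level``, linearly interpolated.

    Returns NaN if the curve never reaches ``level`` from below (a curve that
    starts at or above the level counts as crossing at its first sample).
    """
    above = e >= level
    if not above.any():
        return np.nan
    i = int(np.argmax(above))
    if i == 0:
        return t[0]
    e0, e1 = e[i - 1], e[i]
    if e1 == e0:
        return t[i]
    return t[i - 1] + (level - e0) / (e1 - e0) * (t[i] - t[i - 1])


def _interp_at(t, e, t_query):
    return float(np.interp(t_query, t, e))


def compute_features(curve, times_s, baseline_frames: int) -> dict:
    """Feature dictionary for a single signal curve."""
    s = np.asarray(curve, dtype=float)
    t = np.asarray(times_s, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times_s must be strictly increasing")
    if s.size - baseline_frames < 2:
        raise ValueError("need at least 2 frames after the baseline window")
    base = s[:baseline_frames].mean()
    e = s[baseline_frames:] - base
    tt = t[baseline_frames:]
    t_start = tt[0]

    imax = int(np.argmax(e))
    smax = float(e[imax])
    ttp = float(tt[imax] - t_start)
    auc = float(np.trapezoid(e, tt))

    t_end60 = t_start + AUC60_WINDOW_S
    if t_end60 >= tt[-1]:
        auc60 = auc
    else:
        j = int(np.searchsorted(tt, t_end60))
        e_cut = _interp_at(tt, e, t_end60)
        tt60 = np.append(tt[:j], t_end60)
        e60 = np.append(e[:j], e_cut)
        auc60 = float(np.trapezoid(e60, tt60))

    if smax > 0:
        t10 = _first_upward_crossing(tt, e, 0.1 * smax)
        t90 = _first_upward_crossing(tt, e, 0.9 * smax)
        if np.isfinite(t10) and np.isfinite(t90) and t90 > t10:
            wash_in = 0.8 * smax / (t90 - t10)
        else:
            wash_in = np.nan
    else:
        wash_in = np.nan

    if imax == e.size - 1:
        wash_out = np.nan
    else:
        wash_out = float((e[-1] - smax) / (tt[-1] - tt[imax]))

    return {
        "smax": smax,
        "ttp": ttp,
        "auc": auc,
        "auc60": auc60,
        "wash_in": wash_in,
        "wash_out": wash_out,
    }


def compute_feature_maps(curves, times_s, baseline_frames: int) -> dict:
    """Features for a stack of curves (n_voxels, n_frames) -> dict of arrays."""
    curves = np.asarray(curves, dtype=float)
    out = {k: np.empty(curves.shape[0]) for k in FEATURE_NAMES}
    for v in range(curves.shape[0]):
        f = compute_features(curves[v], times_s, baseline_frames)
        for k in FEATURE_NAMES:
            out[k][v] = f[k]
    return out


def normalize_map(values, mask=None, name: str = "parameter"):
    """Min-max scale to [0, 1] over the (masked) defined voxels.

    ``x_norm = (x - x_min) / (x_max - x_min)``; NaNs stay NaN. Raises for a
    constant map (zero range), naming the offending parameter.
    """
    vals = np.asarray(values, dtype=float)
    sel = np.ones(vals.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    inside = vals[sel]
    inside = inside[np.isfinite(inside)]
    if inside.size < 2:
        raise ValueError(f"cannot normalize '{name}': fewer than 2 defined voxels")
    vmin, vmax = inside.min(), inside.max()
    if vmax == vmin:
        raise ValueError(f"cannot normalize '{name}': constant map (range is zero)")
    return (vals - vmin) / (vmax - vmin)
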