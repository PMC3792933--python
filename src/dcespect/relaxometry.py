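"""Variable-TR T1 mapping and SPGR signal <-> gadolinium concentration conversion.

Two signal models are used:

* saturation recovery, ``S(TR) = S0 * (1 - exp(-TR/T1))``, for the 90-degree
  flip calibration scans acquired at several repetition times;
* the spoiled gradient-echo (SPGR) steady state,
  ``S = s * sin(a) * (1 - E1) / (1 - cos(a) * E1)`` with
  ``E1 = exp(-TR * R1)``, for the low-flip dynamic series.

Concentration couples linearly to the relaxation rate:
``R1(t) = 1/T10 + r1 * C(t)``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "T10Map",
    "fit_t10",
    "spgr_signal",
    "concentration_to_signal",
    "signal_to_concentration",
]

T1_BOUNDS_MS = (50.0, 5000.0)

# Concentrations below this floor are treated as gross inversion failures;
# anything between the floor and zero is residual noise and clipped to zero.
NEGATIVE_CONC_FLOOR_MM = -0.05


@dataclass
class T10Map:
    """Pre-contrast T1 fit result. ``fit_ok`` is False where the fit failed."""

    t1_ms: np.ndarray
    s0: np.ndarray
    fit_ok: np.ndarray


def _profiled_rss(signals: np.ndarray, trs_ms: np.ndarray, t1_ms: np.ndarray):
    """RSS of the saturation-recovery fit with S0 profiled out analytically.

    ``signals`` is (V, nTR); ``t1_ms`` is (V,) or scalar. Returns (rss, s0).
    """
    f = 1.0 - np.exp(-trs_ms / np.asarray(t1_ms, dtype=float)[..., None])
    num = np.einsum("...i,...i->...", signals, f)
    den = np.einsum("...i,...i->...", f, f)
    s0 = num / den
    ss = np.einsum("...i,...i->...", signals, signals)
    rss = ss - s0 * num
    return rss, s0


def fit_t10(volumes, trs_ms, t1_bounds_ms=T1_BOUNDS_MS) -> T10Map:
    """Per-voxel least-squares fit of ``S(TR) = S0 * (1 - exp(-TR/T1))``.

    ``volumes``: sequence of same-shaped arrays, one per TR, or an array whose
    last axis enumerates TRs. Uses a vectorized bracketed search on T1 (S0 is
    profiled out in closed form), so the result is deterministic and loop-free
    over voxels. Voxels whose optimum sticks to the T1 bounds, or with
    non-positive fitted S0, are flagged ``fit_ok = False``.
    """
    trs_ms = np.asarray(trs_ms, dtype=float)
    if trs_ms.size < 3 or np.unique(trs_ms).size < 3:
        raise ValueError("at least 3 distinct TRs are required for the T1 fit")
    if isinstance(volumes, np.ndarray) and volumes.ndim >= 1 and volumes.shape[-1] == trs_ms.size:
        stack = np.asarray(volumes, dtype=float)
    else:
        stack = np.stack([np.asarray(v, dtype=float) for v in volumes], axis=-1)
    if stack.shape[-1] != trs_ms.size:
        raise ValueError("number of volumes must match number of TRs")
    shape = stack.shape[:-1]
    signals = stack.reshape(-1, trs_ms.size)
    nv = signals.shape[0]

    lo_b, hi_b = t1_bounds_ms
    # stage 1: shared log grid
    n_grid = 60
    grid = np.geomspace(lo_b, hi_b, n_grid)
    best_rss = np.full(nv, np.inf)
    best_idx = np.zeros(nv, dtype=int)
    for j, t1 in enumerate(grid):
        rss, _ = _profiled_rss(signals, trs_ms, np.full(nv, t1))
        better = rss < best_rss
        best_rss[better] = rss[better]
        best_idx[better] = j
    step = grid[1] / grid[0]
    lo = grid[best_idx] / step
    hi = grid[best_idx] * step
    # stages 2..4: per-voxel zoom (21 candidates each, bracket shrinks ~10x/stage)
    for _ in range(3):
        n_cand = 21
        cands = lo[:, None] * (hi / lo)[:, None] ** (np.arange(n_cand) / (n_cand - 1))
        best_rss = np.full(nv, np.inf)
        best_t1 = cands[:, 0].copy()
        for j in range(n_cand):
            rss, _ = _profiled_rss(signals, trs_ms, cands[:, j])
            better = rss < best_rss
            best_rss[better] = rss[better]
            best_t1[better] = cands[better, j]
        substep = (hi / lo) ** (1.0 / (n_cand - 1))
        lo = best_t1 / substep
        hi = best_t1 * substep
    t1 = np.clip(best_t1, lo_b, hi_b)
    _, s0 = _profiled_rss(signals, trs_ms, t1)
    ok = (t1 > lo_b * 1.01) & (t1 < hi_b * 0.99) & (s0 > 0) & np.isfinite(t1)
    return T10Map(
        t1_ms=t1.reshape(shape),
        s0=s0.reshape(shape),
        fit_ok=ok.reshape(shape),
    )


def _check_spgr_args(t10_ms, flip_deg):
    if np.any(np.asarray(t10_ms) <= 0):
        raise ValueError("t10_ms must be positive")
    if np.isclose(np.sin(np.deg2rad(flip_deg)), 0.0):
        raise ValueError("flip angle must not be 0 (or a multiple of 180)")


def spgr_signal(conc_mM, t10_ms, r1, tr_ms, flip_deg, s_scale=1.0):
    """SPGR steady-state signal for concentration ``conc_mM`` (broadcasts)."""
    _check_spgr_args(t10_ms, flip_deg)
    conc = np.asarray(conc_mM, dtype=float)
    r1_rate = 1000.0 / np.asarray(t10_ms, dtype=float) + r1 * conc  # 1/s
    e1 = np.exp(-(tr_ms / 1000.0) * r1_rate)
    a = np.deg2rad(flip_deg)
    return s_scale * np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1)


def concentration_to_signal(conc_mM, t10_ms, r1, tr_ms, flip_deg, s_scale=1.0):
    """Forward model for the dynamic series (alias of :func:`spgr_signal`)."""
    return spgr_signal(conc_mM, t10_ms, r1, tr_ms, flip_deg, s_scale)


def signal_to_concentration(
    signal,
    t10_ms,
    r1,
    tr_ms,
    flip_deg,
    baseline_frames: int,
):
    """Invert the SPGR equation per frame and convert R1 to concentration.

    The equilibrium scale is calibrated from the mean of the first
    ``baseline_frames`` frames (assumed pre-contrast, C = 0). Frames whose
    signal falls outside the invertible SPGR range are returned as NaN.
    Negative concentrations are clamped at ``NEGATIVE_CONC_FLOOR_MM`` and the
    remaining negative residual set to zero.

    ``signal``: array (..., n_frames); ``t10_ms`` broadcasts over the leading
    axes. Returns an array of the same shape as ``signal``.
    """
    _check_spgr_args(t10_ms, flip_deg)
    if baseline_frames < 1:
        raise ValueError("baseline_frames must be >= 1")
    sig = np.asarray(signal, dtype=float)
    t10 = np.asarray(t10_ms, dtype=float)
    tr_s = tr_ms / 1000.0
    a = np.deg2rad(flip_deg)
    sa, ca = np.sin(a), np.cos(a)

    s_base = sig[..., :baseline_frames].mean(axis=-1)
    e10 = np.exp(-tr_s * 1000.0 / t10)
    g0 = sa * (1.0 - e10) / (1.0 - ca * e10)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = s_base / g0
        x = sig / scale[..., None]
        e1 = (sa - x) / (sa - ca * x)
        valid = (e1 > 0.0) & (e1 < 1.0) & np.isfinite(e1)
        r1_rate = np.where(valid, -np.log(np.where(valid, e1, 0.5)) / tr_s, np.nan)
        conc = (r1_rate - 1000.0 / t10[..., None]) / r1
    conc = np.clip(conc, NEGATIVE_CONC_FLOOR_MM, None)
    conc = np.where(conc < 0.0, 0.0, conc)
    return conc
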