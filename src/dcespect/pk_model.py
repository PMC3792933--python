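"""Standard two-parameter compartment model (Ktrans, kep) and bi-exponential
arterial input function.

The tissue curve is the convolution of the plasma curve with an exponential
residue::

    Ct(t) = Ktrans * int_0^t Cp(tau) * exp(-kep * (t - tau)) d tau

which has a closed form when Cp is a sum of exponentials. Voxels with no or
very little enhancement fit poorly and produce non-physiological rates; an
enhancement gate zeroes Ktrans and kep there.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "AifModel",
    "fit_aif",
    "tofts_forward",
    "fit_tofts",
    "fit_tofts_map",
    "apply_enhancement_gate",
]


@dataclass
class AifModel:
    """Bi-exponential plasma input: zero before ``t_arrival_s``, then
    ``a1*exp(-m1*tau) + a2*exp(-m2*tau)`` with ``tau = t - t_arrival_s``.

    Amplitudes in mM, rates in 1/s. Convention: ``m1 >= m2`` (fast, slow).
    """

    a1: float
    m1: float
    a2: float
    m2: float
    t_arrival_s: float = 0.0

    def __post_init__(self) -> None:
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("AIF amplitudes must be non-negative")
        if self.m1 <= 0 or self.m2 <= 0:
            raise ValueError("AIF decay rates must be positive")

    def cp(self, times_s) -> np.ndarray:
        """Plasma concentration at the given times (vectorized)."""
        tau = np.asarray(times_s, dtype=float) - self.t_arrival_s
        out = self.a1 * np.exp(-self.m1 * np.maximum(tau, 0.0)) + self.a2 * np.exp(
            -self.m2 * np.maximum(tau, 0.0)
        )
        return np.where(tau < 0.0, 0.0, out)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AifModel":
        return cls(**d)


def _exp_conv(amp, m, kep, tau):
    """Closed form of ``int_0^tau amp*exp(-m s) * exp(-kep (tau - s)) ds``.

    Uses the ``tau * exp(-m tau)`` limit when kep is numerically equal to m.
    """
    d = kep - m
    near = np.abs(d) < 1e-10
    safe = np.where(near, 1.0, d)
    gen = amp * (np.exp(-m * tau) - np.exp(-kep * tau)) / safe
    lim = amp * tau * np.exp(-m * tau)
    return np.where(near, lim, gen)


def tofts_forward(ktrans, kep, aif: AifModel, times_s) -> np.ndarray:
    """Analytic tissue concentration for the bi-exponential AIF.

    ``ktrans``/``kep`` may be scalars or arrays broadcasting against each
    other; the result gains a trailing time axis. Scalar inputs are validated
    to be non-negative.
    """
    kt = np.asarray(ktrans, dtype=float)
    ke = np.asarray(kep, dtype=float)
    if kt.ndim == 0 and (kt < 0 or ke < 0):
        raise ValueError("ktrans and kep must be non-negative")
    t = np.asarray(times_s, dtype=float)
    tau = np.maximum(t - aif.t_arrival_s, 0.0)
    ke_b = ke[..., None] if ke.ndim else ke
    kt_b = kt[..., None] if kt.ndim else kt
    ct = kt_b * (
        _exp_conv(aif.a1, aif.m1, ke_b, tau) + _exp_conv(aif.a2, aif.m2, ke_b, tau)
    )
    return ct


def fit_aif(artery_curves, times_s) -> AifModel:
    """Fit the bi-exponential input to the average of artery voxel curves.

    Arrival is the first time the averaged curve exceeds 10% of its maximum;
    the two exponentials are fit by bounded least squares for ``t >= arrival``
    from several starts, and ordered fast/slow afterwards.
    """
    curves = np.atleast_2d(np.asarray(artery_curves, dtype=float))
    times = np.asarray(times_s, dtype=float)
    avg = np.nanmean(curves, axis=0)
    if not np.any(np.nan_to_num(avg) > 0):
        raise ValueError("artery curve is zero everywhere; cannot fit AIF")
    finite = np.isfinite(avg)
    peak = np.nanmax(avg)
    above = finite & (avg > 0.1 * peak)
    t_arrival = float(times[np.argmax(above)])
    sel = finite & (times >= t_arrival)
    t_fit = times[sel] - t_arrival
    y = avg[sel]

    def resid(p):
        a1, m1, a2, m2 = p
        return a1 * np.exp(-m1 * t_fit) + a2 * np.exp(-m2 * t_fit) - y

    best = None
    starts = [(0.05, 0.005), (0.02, 0.002), (0.01, 0.001), (0.1, 0.01)]
    for m1_0, m2_0 in starts:
        x0 = [0.7 * y[0], m1_0, 0.3 * y[0], m2_0]
        res = least_squares(
            resid,
            x0,
            bounds=([0, 1e-8, 0, 1e-8], [np.inf, 10.0, np.inf, 10.0]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=2000,
        )
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        raise RuntimeError(
            f"AIF fit failed: status={getattr(best, 'status', None)}, "
            f"cost={getattr(best, 'cost', None)}, message={getattr(best, 'message', '')}"
        )
    a1, m1, a2, m2 = best.x
    if m1 < m2:
        a1, m1, a2, m2 = a2, m2, a1, m1
    return AifModel(a1=a1, m1=max(m1, 1e-8), a2=a2, m2=max(m2, 1e-8), t_arrival_s=t_arrival)


_TOFTS_STARTS = [(1e-4, 1e-3), (1e-3, 1e-2), (1e-2, 1e-1)]
_TOFTS_BOUNDS = ([0.0, 0.0], [1.0, 1.0])


def fit_tofts(curve, aif: AifModel, times_s):
    """Bounded non-linear least squares for one voxel.

    Multi-start from ``_TOFTS_STARTS``; ties broken by lowest RSS, then lowest
    ktrans. Never raises for pathological curves: the best bounded solution is
    returned and left to the downstream enhancement gate.

    Returns ``(ktrans, kep, rss)``.
    """
    y = np.asarray(curve, dtype=float)
    t = np.asarray(times_s, dtype=float)
    good = np.isfinite(y)
    yv, tv = y[good], t[good]

    def resid(p):
        return tofts_forward(p[0], p[1], aif, tv) - yv

    candidates = []
    for x0 in _TOFTS_STARTS:
        res = least_squares(
            resid, x0, bounds=_TOFTS_BOUNDS, xtol=1e-12, ftol=1e-12, gtol=1e-12,
            max_nfev=500,
        )
        candidates.append((2.0 * res.cost, res.x[0], res.x[1]))
    candidates.sort(key=lambda c: (c[0], c[1]))
    rss, kt, kep = candidates[0]
    return float(kt), float(kep), float(rss)


def fit_tofts_map(curves, aif: AifModel, times_s, kep_bounds=(1e-4, 1.0)):
    """Vectorized fit for many voxels via variable projection.

    For fixed kep the model is linear in ktrans, so ktrans is solved in closed
    form and only kep is searched: a shared log grid followed by per-voxel
    bracket refinement, all vectorized across voxels. Equivalent in optimum to
    the per-voxel multi-start fit but orders of magnitude faster.

    ``curves``: (n_voxels, n_frames), NaNs allowed (treated as missing).
    Returns ``(ktrans, kep, rss)`` arrays of length n_voxels.
    """
    y = np.asarray(curves, dtype=float)
    if y.ndim != 2:
        raise ValueError("curves must be 2D (voxels, frames)")
    t = np.asarray(times_s, dtype=float)
    w = np.isfinite(y)
    y0 = np.where(w, y, 0.0)
    ss_y = np.einsum("vt,vt->v", y0, y0)
    nv = y.shape[0]

    def score(kep_vec):
        """Profile ktrans out; returns (rss, ktrans) for per-voxel kep."""
        b = tofts_forward(np.ones(nv), kep_vec, aif, t)
        b = np.where(w, b, 0.0)
        num = np.einsum("vt,vt->v", y0, b)
        den = np.einsum("vt,vt->v", b, b)
        with np.errstate(divide="ignore", invalid="ignore"):
            kt = np.where(den > 0, num / den, 0.0)
        kt = np.clip(kt, 0.0, 1.0)
        rss = ss_y - 2.0 * kt * num + kt**2 * den
        return rss, kt

    lo_b, hi_b = kep_bounds
    grid = np.geomspace(lo_b, hi_b, 50)
    best_rss = np.full(nv, np.inf)
    best_kep = np.full(nv, grid[0])
    best_kt = np.zeros(nv)
    for kep_val in grid:
        rss, kt = score(np.full(nv, kep_val))
        better = rss < best_rss - 1e-300
        best_rss[better] = rss[better]
        best_kep[better] = kep_val
        best_kt[better] = kt[better]
    step = grid[1] / grid[0]
    lo = np.clip(best_kep / step, lo_b, hi_b)
    hi = np.clip(best_kep * step, lo_b, hi_b)
    for _ in range(4):
        n_cand = 15
        ratio = (hi / lo) ** (1.0 / (n_cand - 1))
        for j in range(n_cand):
            kep_vec = lo * ratio**j
            rss, kt = score(kep_vec)
            better = rss < best_rss
            best_rss[better] = rss[better]
            best_kep[better] = kep_vec[better]
            best_kt[better] = kt[better]
        lo = np.clip(best_kep / ratio, lo_b, hi_b)
        hi = np.clip(best_kep * ratio, lo_b, hi_b)
    zero = best_kt <= 0.0
    best_kt[zero] = 0.0
    best_rss = np.where(zero, ss_y, best_rss)
    return best_kt, best_kep, best_rss


def apply_enhancement_gate(ktrans, kep, smax, mask, threshold_frac=0.1):
    """Zero the rate maps where peak enhancement is negligible.

    The threshold is ``threshold_frac`` times a robust maximum (98th
    percentile) of in-mask Smax. Returns ``(ktrans, kep, gated)`` where
    ``gated`` marks the zeroed voxels.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must be in (0, 1)")
    mask = np.asarray(mask, dtype=bool)
    smax = np.asarray(smax, dtype=float)
    robust_max = np.nanpercentile(smax[mask], 98)
    gated = mask & ~(smax >= threshold_frac * robust_max)
    kt = np.array(ktrans, dtype=float, copy=True)
    ke = np.array(kep, dtype=float, copy=True)
    kt[gated] = 0.0
    ke[gated] = 0.0
    return kt, ke, gated
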