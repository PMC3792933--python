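"""Mask-based rigid + affine registration and map resampling.

Stage 1 aligns centroids and principal axes of the two binary masks (second
moments; eigenvector signs disambiguated by the third moment along each axis).
Stage 2 refines all 12 affine parameters by maximizing a soft Dice overlap
with a derivative-free local optimizer. Everything operates in world (mm)
coordinates via the NIfTI affines, so anisotropic grids are handled
transparently.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import minimize

from .core import world_to_voxel

__all__ = ["AffineTransform", "register_masks", "resample_map", "dice"]


@dataclass
class AffineTransform:
    """World-coordinate transform ``x_fixed = matrix @ x_moving + translation``."""

    matrix: np.ndarray
    translation: np.ndarray
    kind: str = "affine"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        det = np.linalg.det(self.matrix)
        if self.kind == "rigid":
            if not (np.allclose(self.matrix @ self.matrix.T, np.eye(3), atol=1e-6)
                    and abs(det - 1.0) < 1e-6):
                raise ValueError("rigid transform requires an orthogonal matrix with det=+1")
        elif abs(det) < 1e-12:
            raise ValueError("affine transform matrix is singular")

    @classmethod
    def identity(cls, kind: str = "rigid") -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3), kind=kind)

    @classmethod
    def rigid_z(cls, rotation_deg: float, translation) -> "AffineTransform":
        """Rotation about the world z axis followed by a translation."""
        a = np.deg2rad(rotation_deg)
        c, s = np.cos(a), np.sin(a)
        m = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        return cls(m, np.asarray(translation, dtype=float), kind="rigid")

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform":
        minv = np.linalg.inv(self.matrix)
        return AffineTransform(minv, -minv @ self.translation, kind=self.kind)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return ``self o other`` (apply ``other`` first)."""
        kind = "rigid" if self.kind == other.kind == "rigid" else "affine"
        return AffineTransform(
            self.matrix @ other.matrix,
            self.matrix @ other.translation + self.translation,
            kind=kind,
        )

    def as_homogeneous(self) -> np.ndarray:
        h = np.eye(4)
        h[:3, :3] = self.matrix
        h[:3, 3] = self.translation
        return h

    def to_json(self) -> str:
        return json.dumps(
            {"kind": self.kind, "matrix_mm_ras": self.as_homogeneous().tolist()}
        )

    @classmethod
    def from_json(cls, s: str) -> "AffineTransform":
        d = json.loads(s)
        h = np.asarray(d["matrix_mm_ras"])
        return cls(h[:3, :3], h[:3, 3], kind=d.get("kind", "affine"))


def _mask_world_points(mask, affine):
    ijk = np.argwhere(mask)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def _principal_axes(points):
    """Centroid, eigenvalues (ascending), eigenvectors, axis skewness."""
    c = points.mean(axis=0)
    centered = points - c
    cov = centered.T @ centered / len(points)
    evals, evecs = np.linalg.eigh(cov)
    if np.linalg.det(evecs) < 0:
        evecs[:, 0] = -evecs[:, 0]
    proj = centered @ evecs
    skew = (proj**3).mean(axis=0)
    return c, evals, evecs, skew


def _resample_soft(moving, moving_affine, transform, fixed_shape, fixed_affine,
                   order=1):
    """Moving image sampled on the fixed grid through ``transform`` (float)."""
    idx = np.indices(fixed_shape, dtype=float).reshape(3, -1).T
    world_f = idx @ fixed_affine[:3, :3].T + fixed_affine[:3, 3]
    world_m = transform.inverse().apply(world_f)
    vox_m = world_to_voxel(moving_affine, world_m)
    vals = map_coordinates(
        np.asarray(moving, dtype=float), vox_m.T, order=order, mode="constant",
        cval=0.0,
    )
    return vals.reshape(fixed_shape)


def dice(a, b) -> float:
    """Soft Dice overlap between two (possibly fractional) masks."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * (a * b).sum() / denom)


def register_masks(moving_mask, fixed_mask, moving_affine=None, fixed_affine=None,
                   refine: bool = True) -> AffineTransform:
    """Recover the world transform that maps the moving mask onto the fixed one.

    Stage 1 (rigid): centroid + principal-axes alignment with skewness-based
    sign disambiguation. Stage 2 (affine): Powell refinement of all 12
    parameters maximizing soft Dice. Degenerate masks (fewer than 4 voxels or
    near-coplanar) fall back to a centroid translation with a warning.
    """
    moving_mask = np.asarray(moving_mask, dtype=bool)
    fixed_mask = np.asarray(fixed_mask, dtype=bool)
    if not moving_mask.any() or not fixed_mask.any():
        raise ValueError("masks must be non-empty")
    if moving_affine is None:
        moving_affine = np.eye(4)
    if fixed_affine is None:
        fixed_affine = np.eye(4)

    pts_m = _mask_world_points(moving_mask, moving_affine)
    pts_f = _mask_world_points(fixed_mask, fixed_affine)
    c_m, ev_m, v_m, sk_m = _principal_axes(pts_m)
    c_f, ev_f, v_f, sk_f = _principal_axes(pts_f)

    degenerate = len(pts_m) < 4 or len(pts_f) < 4 or ev_m[0] < 1e-9 or ev_f[0] < 1e-9
    if degenerate:
        warnings.warn(
            "degenerate mask geometry; falling back to centroid translation",
            stacklevel=2,
        )
        rigid = AffineTransform(np.eye(3), c_f - c_m, kind="rigid")
    else:
        signs = np.ones(3)
        strength = np.abs(sk_m * sk_f)
        for i in range(3):
            if strength[i] > 1e-9:
                signs[i] = np.sign(sk_m[i] * sk_f[i])
        if np.prod(signs) < 0:
            signs[int(np.argmin(strength))] *= -1
        rot = v_f @ np.diag(signs) @ v_m.T
        if np.linalg.det(rot) < 0:  # safety; should not trigger after sign fix
            signs[int(np.argmin(strength))] *= -1
            rot = v_f @ np.diag(signs) @ v_m.T
        rigid = AffineTransform(rot, c_f - rot @ c_m, kind="rigid")

    if not refine:
        return rigid

    # refine on a crop around the fixed mask: the soft-Dice objective only
    # sees voxels near the target, which cuts the resampling cost sharply
    ijk_f = np.argwhere(fixed_mask)
    lo_c = np.maximum(ijk_f.min(axis=0) - 6, 0)
    hi_c = np.minimum(ijk_f.max(axis=0) + 7, fixed_mask.shape)
    crop = tuple(slice(l, h) for l, h in zip(lo_c, hi_c))
    crop_affine = np.asarray(fixed_affine).copy()
    crop_affine[:3, 3] += crop_affine[:3, :3] @ lo_c
    fshape = tuple(h - l for l, h in zip(lo_c, hi_c))
    f_float = fixed_mask[crop].astype(float)
    fixed_affine = crop_affine

    def objective(p):
        m = (np.eye(3) + p[:9].reshape(3, 3)) @ rigid.matrix
        t = rigid.translation + p[9:]
        try:
            tr = AffineTransform(m, t, kind="affine")
        except ValueError:
            return 1.0
        mv = _resample_soft(moving_mask, moving_affine, tr, fshape, fixed_affine)
        return 1.0 - dice(mv, f_float)

    if objective(np.zeros(12)) < 1e-9:
        return rigid

    res = minimize(
        objective,
        np.zeros(12),
        method="Powell",
        options={"xtol": 1e-4, "ftol": 1e-7, "maxiter": 40},
    )
    p = res.x
    matrix = (np.eye(3) + p[:9].reshape(3, 3)) @ rigid.matrix
    translation = rigid.translation + p[9:]
    return AffineTransform(matrix, translation, kind="affine")


def resample_map(values, source_affine, transform: AffineTransform, ref_shape,
                 ref_affine, order: int = 1):
    """Resample a map defined on the source grid onto a reference grid.

    ``transform`` maps source-world to reference-world coordinates. Continuous
    maps use trilinear interpolation (``order=1``) with NaN propagation:
    voxels mapping outside the source, or touching undefined source voxels,
    come back undefined. Masks and label maps should use ``order=0``.
    """
    vals = np.asarray(values, dtype=float)
    idx = np.indices(tuple(ref_shape), dtype=float).reshape(3, -1).T
    world_r = idx @ np.asarray(ref_affine)[:3, :3].T + np.asarray(ref_affine)[:3, 3]
    world_s = transform.inverse().apply(world_r)
    vox_s = world_to_voxel(np.asarray(source_affine), world_s)
    cval = 0.0 if order == 0 else np.nan
    out = map_coordinates(vals, vox_s.T, order=order, mode="constant", cval=cval)
    if order == 0:
        # nearest-neighbour: flag out-of-bounds queries as undefined for floats
        inside = np.all((vox_s > -0.5) & (vox_s < np.array(vals.shape) - 0.5), axis=1)
        out = np.where(inside, out, 0.0 if np.asarray(values).dtype == bool else np.nan)
    return out.reshape(tuple(ref_shape))
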