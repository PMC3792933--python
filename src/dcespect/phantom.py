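"""Synthetic dual-modality study generator.

Produces a heterogeneous ellipsoidal tumor with smooth Ktrans / ve fields, a
contiguous non-enhancing pocket, receptor-free vessel septa, a feeding-artery
region, a variable-TR calibration stack, a two-block dynamic contrast series,
and an uptake volume on a coarser, rigidly displaced grid. Uptake follows a
saturating (Michaelis-Menten-type) function of an early-delivery surrogate
(area under the first 60 s of the true concentration curve), then resolution
blur and counting noise are applied — the statistical structure the
downstream correlation analysis assumes: exchange-related curve features track
uptake monotonically while amount-related features saturate.

All randomness derives from ``PhantomConfig.seed``; identical configs give
bit-identical studies.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .core import TimedVolumeSeries, dce_time_vector, default_affine, world_to_voxel
from .pk_model import AifModel, tofts_forward
from .registration import AffineTransform
from .relaxometry import spgr_signal

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "SyntheticStudy",
    "generate_parameter_fields",
    "simulate_dce",
    "simulate_t1_calibration",
    "simulate_spect",
    "simulate_study",
    "peak_enhancement",
    "noise_sd_for_snr",
]


@dataclass
class PhantomConfig:
    # grid / timing
    grid_shape: tuple = (42, 42, 18)
    voxel_size_mm: tuple = (0.4, 0.4, 0.8)
    n_frames: int = 96
    frame_interval_s: float = 4.3
    gap_after_frame: int = 48
    gap_s: float = 60.0
    # acquisition
    t1_trs_ms: tuple = (200.0, 400.0, 800.0, 1200.0, 2400.0)
    flip_angle_deg: float = 10.0
    tr_dce_ms: float = 3.4
    r1_relaxivity: float = 4.5  # / mM / s
    s_scale: float = 500.0
    noise_sd: float = 0.2  # additive signal noise, same units as the series
    calib_noise_sd: float = 0.0
    # contrast kinetics
    arrival_s: float = 7 * 4.3  # bolus arrival ~30 s, exactly on frame 7
    aif_a1: float = 3.0
    aif_m1: float = 0.010
    aif_a2: float = 1.0
    aif_m2: float = 0.0015
    # tissue fields
    tumor_semiaxes_mm: tuple = (4.6, 3.8, 4.4)
    kt_max: float = 0.009  # 1/s
    ve_range: tuple = (0.22, 0.65)
    ve_power: float = 0.6  # shape of the ve decline with Ktrans
    ve_noise: float = 0.10  # independent smooth variability of ve
    field_smooth_mm: float = 2.0
    pocket_radius_mm: float = 1.3
    # receptor-poor but well-perfused pockets (occult septa): high ve and
    # Ktrans yet almost no binding, left inside the analysis mask
    septa_frac: float = 0.15  # fraction of analyzable tumor they occupy
    septa_receptor: float = 0.03  # relative receptor availability there
    septa_ve: float = 0.68
    # uptake generation
    spect_umax_kbq: float = 50.0
    spect_d50: float | str = "auto"  # mM*s, or "auto" (fraction of median delivery)
    spect_d50_frac: float = 0.85
    spect_fwhm_mm: float = 1.5
    spect_downsample: float = 2.5
    spect_counts_per_kbq: float = 60.0  # 0 disables Poisson noise
    # inter-modality displacement (MRI world -> SPECT/CT world)
    transform_rot_z_deg: float = 4.0
    transform_translation_mm: tuple = (1.1, -0.7, 0.5)
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if len(self.t1_trs_ms) < 3:
            raise ValueError("need at least 3 calibration TRs")
        if not isinstance(self.spect_d50, str) and self.spect_d50 <= 0:
            raise ValueError("spect_d50 must be positive")
        if self.spect_downsample < 1:
            raise ValueError("spect_downsample must be >= 1")
        # check the tumor (and its pocket) fit on the grid
        extent = np.asarray(self.grid_shape) * np.asarray(self.voxel_size_mm)
        needed = 2.0 * np.asarray(self.tumor_semiaxes_mm) + 2.0
        if np.any(extent < needed):
            min_shape = np.ceil(needed / np.asarray(self.voxel_size_mm)).astype(int)
            raise ValueError(
                f"grid too small for the tumor: need at least shape {tuple(min_shape)}"
            )
        if min(self.tumor_semiaxes_mm) < 2.0 * self.pocket_radius_mm:
            min_ax = 2.0 * self.pocket_radius_mm
            min_shape = tuple(
                int(np.ceil((2 * min_ax + 2.0) / v)) for v in self.voxel_size_mm
            )
            raise ValueError(
                "tumor too small to place the low-enhancement pocket: smallest "
                f"semi-axis must be >= {min_ax:g} mm (grid shape >= {min_shape})"
            )
        dce_time_vector(self.n_frames, self.frame_interval_s,
                        self.gap_after_frame, self.gap_s)

    # -- derived helpers -------------------------------------------------
    @property
    def affine(self) -> np.ndarray:
        return default_affine(self.voxel_size_mm)

    def times_s(self) -> np.ndarray:
        return dce_time_vector(self.n_frames, self.frame_interval_s,
                               self.gap_after_frame, self.gap_s)

    def aif(self) -> AifModel:
        return AifModel(a1=self.aif_a1, m1=self.aif_m1, a2=self.aif_a2,
                        m2=self.aif_m2, t_arrival_s=self.arrival_s)

    def applied_transform(self) -> AffineTransform:
        return AffineTransform.rigid_z(self.transform_rot_z_deg,
                                       self.transform_translation_mm)

    def baseline_frames(self) -> int:
        return int(np.sum(self.times_s() < self.arrival_s))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    ktrans_map: np.ndarray  # 1/s
    kep_map: np.ndarray  # 1/s
    ve_map: np.ndarray
    t10_map: np.ndarray  # ms
    tumor_mask: np.ndarray
    vessel_mask: np.ndarray
    artery_mask: np.ndarray
    septa_mask: np.ndarray  # receptor-poor, well-perfused (in analysis mask)
    receptor_map: np.ndarray  # relative receptor availability
    spect_truth: np.ndarray  # noiseless, pre-blur uptake (kBq/voxel)
    delivery: np.ndarray  # delivery surrogate (mM*s)


@dataclass
class SyntheticStudy:
    dce: TimedVolumeSeries
    t1_volumes: list
    t1_trs_ms: tuple
    spect: np.ndarray
    spect_affine: np.ndarray
    ct_tumor_mask: np.ndarray
    ct_vessel_mask: np.ndarray
    ct_affine: np.ndarray
    applied_transform: AffineTransform
    ground_truth: GroundTruth
    config: PhantomConfig = field(repr=False, default=None)


def _smooth_unit_field(rng, shape, sigma_vox):
    """Smoothed standard-normal field, re-standardized."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    return (f - f.mean()) / f.std()


def _world_grid(config):
    idx = np.indices(config.grid_shape, dtype=float)
    vox = np.asarray(config.voxel_size_mm)
    return [idx[i] * vox[i] for i in range(3)]


def _delivery_surrogate(ktrans, kep, aif, window_s=60.0, dt=0.5):
    """AUC over the first ``window_s`` seconds (post-arrival) of the noiseless
    tissue concentration curve — the early-delivery surrogate driving uptake."""
    tau = np.arange(0.0, window_s + dt / 2, dt) + aif.t_arrival_s
    ct = tofts_forward(np.ravel(ktrans), np.ravel(kep), aif, tau)
    return np.trapezoid(ct, tau, axis=-1).reshape(np.shape(ktrans))


def generate_parameter_fields(config: PhantomConfig) -> GroundTruth:
    """Ground-truth tissue fields, masks, and the noiseless uptake map."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.grid_shape)
    vox = np.asarray(config.voxel_size_mm)
    x, y, z = _world_grid(config)
    center = (np.asarray(shape) - 1) * vox / 2.0

    ax = np.asarray(config.tumor_semiaxes_mm)
    # egg-shaped tumor: the y and z semi-axes taper along x and y respectively,
    # giving non-zero third moments about every principal axis so that
    # mask-based registration has no 180-degree orientation ambiguity
    xn = (x - center[0]) / ax[0]
    ay_eff = ax[1] * (1.0 - 0.22 * np.clip(xn, -1.2, 1.2))
    yn = (y - center[1]) / ax[1]
    az_eff = ax[2] * (1.0 - 0.18 * np.clip(yn, -1.2, 1.2))
    r2 = (xn**2 + ((y - center[1]) / ay_eff) ** 2
          + ((z - center[2]) / az_eff) ** 2)
    tumor = r2 <= 1.0

    # feeding artery: small cylinder along z, clear of the tumor
    art_center = center + np.array([ax[0] + 1.6, 0.0, 0.0])
    art = ((x - art_center[0]) ** 2 + (y - art_center[1]) ** 2) <= 0.8**2
    artery = art & ~tumor

    # vessel septum: thin oblique slab through the tumor (well-perfused,
    # receptor-free connective tissue)
    plane = (x - center[0]) - 0.5 * (y - center[1])
    vessel = tumor & (np.abs(plane - 1.2) < 0.35) & (np.abs(z - center[2]) < 2.6)

    sigma_vox = config.field_smooth_mm / vox
    z1 = _smooth_unit_field(rng, shape, sigma_vox)
    z2 = _smooth_unit_field(rng, shape, sigma_vox)
    z3 = _smooth_unit_field(rng, shape, sigma_vox)

    # Ktrans: probit-uniform over the tumor -> [0, kt_max] (rank-preserving
    # map of the smooth Gaussian field; keeps the top end well populated)
    from scipy.special import ndtr

    zt = z1[tumor]
    kt = np.zeros(shape)
    kt[tumor] = ndtr((z1[tumor] - zt.mean()) / zt.std()) * config.kt_max

    # low-enhancement pocket: contiguous ball with Ktrans exactly zero in the
    # core and a smooth taper outside it
    u = rng.standard_normal(3)
    u /= np.linalg.norm(u)
    pocket_center = center + 0.45 * ax * u
    rp = np.sqrt((x - pocket_center[0]) ** 2 + (y - pocket_center[1]) ** 2
                 + (z - pocket_center[2]) ** 2)
    taper = np.clip((rp - config.pocket_radius_mm) / 0.8, 0.0, 1.0)
    kt *= taper * taper * (3 - 2 * taper)  # smoothstep

    # ve anti-correlated with Ktrans (well-perfused regions drain fast, big
    # pools exchange slowly) plus independent smooth variability
    lo, hi = config.ve_range
    ve = hi - (hi - lo) * (kt / config.kt_max) ** config.ve_power \
        + config.ve_noise * z2
    ve = np.clip(ve, 0.12, 0.68)

    # occult septa: contiguous well-perfused, receptor-poor regions that stay
    # inside the analysis mask (unlike the delineated vessel septum)
    core = tumor & ~vessel
    # keep septa out of the best-perfused tissue so the delivery-uptake link
    # stays intact at the top of the Ktrans range
    eligible = core & (kt < 0.65 * config.kt_max)
    n_target = int(round(config.septa_frac * core.sum()))
    z_thr = np.quantile(z2[eligible], 1.0 - min(n_target / eligible.sum(), 0.9))
    septa = eligible & (z2 > z_thr)
    ve[septa] = config.septa_ve
    receptor = np.ones(shape)
    receptor[septa] = config.septa_receptor

    kt[vessel] = config.kt_max
    ve[vessel] = lo + 1e-3

    with np.errstate(divide="ignore", invalid="ignore"):
        kep = np.where(ve > 0, kt / ve, 0.0)

    t10 = np.clip(1300.0 + 250.0 * z3, 900.0, 2000.0)
    t10[artery] = 1700.0

    delivery = np.zeros(shape)
    sel = tumor
    delivery[sel] = _delivery_surrogate(kt[sel], kep[sel], config.aif())

    if isinstance(config.spect_d50, str):
        d50 = config.spect_d50_frac * float(np.median(delivery[tumor]))
    else:
        d50 = float(config.spect_d50)
    if d50 <= 0:
        raise ValueError("spect_d50 must be positive")
    uptake = np.zeros(shape)
    uptake[tumor] = (receptor[tumor] * config.spect_umax_kbq * delivery[tumor]
                     / (delivery[tumor] + d50))
    uptake[vessel] = 0.0  # receptor-free septa take up nothing

    return GroundTruth(
        ktrans_map=kt, kep_map=kep, ve_map=ve, t10_map=t10,
        tumor_mask=tumor, vessel_mask=vessel, artery_mask=artery,
        septa_mask=septa, receptor_map=receptor,
        spect_truth=uptake, delivery=delivery,
    )


def simulate_dce(truth: GroundTruth, aif: AifModel, config: PhantomConfig) -> TimedVolumeSeries:
    """Noisy dynamic signal series from the ground-truth fields."""
    config.validate()
    times = config.times_s()
    shape = tuple(config.grid_shape)
    conc = np.zeros(shape + (times.size,))
    sel = truth.tumor_mask
    conc[sel] = tofts_forward(truth.ktrans_map[sel], truth.kep_map[sel], aif, times)
    conc[truth.artery_mask] = aif.cp(times)
    signal = spgr_signal(
        conc, truth.t10_map[..., None], config.r1_relaxivity, config.tr_dce_ms,
        config.flip_angle_deg, config.s_scale,
    )
    if config.noise_sd > 0:
        rng = np.random.default_rng([config.seed, 1])
        signal = signal + rng.normal(0.0, config.noise_sd, signal.shape)
    return TimedVolumeSeries(signal, times, affine=config.affine)


def simulate_t1_calibration(truth: GroundTruth, config: PhantomConfig) -> list:
    """Saturation-recovery volumes, one per calibration TR."""
    vols = []
    rng = np.random.default_rng([config.seed, 2])
    for tr in config.t1_trs_ms:
        v = config.s_scale * (1.0 - np.exp(-tr / truth.t10_map))
        if config.calib_noise_sd > 0:
            v = v + rng.normal(0.0, config.calib_noise_sd, v.shape)
        vols.append(v)
    return vols


def _spect_grid(config):
    ds = config.spect_downsample
    shape = tuple(int(np.ceil(s / ds)) for s in config.grid_shape)
    spacing = np.asarray(config.voxel_size_mm) * ds
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = (ds - 1.0) / 2.0 * np.asarray(config.voxel_size_mm)
    return shape, aff


def simulate_spect(truth: GroundTruth, config: PhantomConfig):
    """Uptake volume on the coarse displaced grid: blur, count noise, resample.

    Returns ``(volume, affine)``. The affine lives in the SPECT/CT world frame,
    which is offset from the MRI frame by ``config.applied_transform()``.
    """
    config.validate()
    vox = np.asarray(config.voxel_size_mm)
    img = truth.spect_truth
    if config.spect_fwhm_mm > 0:
        sigma = config.spect_fwhm_mm / 2.354820045 / vox
        img = gaussian_filter(img, sigma=sigma)
    if config.spect_counts_per_kbq > 0:
        rng = np.random.default_rng([config.seed, 3])
        img = rng.poisson(np.maximum(img, 0.0) * config.spect_counts_per_kbq) \
            / config.spect_counts_per_kbq
    shape_s, aff_s = _spect_grid(config)
    idx = np.indices(shape_s, dtype=float).reshape(3, -1).T
    world_f = idx @ aff_s[:3, :3].T + aff_s[:3, 3]
    world_m = config.applied_transform().inverse().apply(world_f)
    vox_m = world_to_voxel(config.affine, world_m)
    vol = map_coordinates(img, vox_m.T, order=1, mode="constant", cval=0.0)
    return vol.reshape(shape_s), aff_s


def _mask_in_ct_frame(mask, config):
    """Nearest-neighbour sample of an MRI-frame mask on the CT-frame grid."""
    idx = np.indices(tuple(config.grid_shape), dtype=float).reshape(3, -1).T
    aff = config.affine
    world_f = idx @ aff[:3, :3].T + aff[:3, 3]
    world_m = config.applied_transform().inverse().apply(world_f)
    vox_m = world_to_voxel(aff, world_m)
    vals = map_coordinates(mask.astype(float), vox_m.T, order=0, mode="constant",
                           cval=0.0)
    return vals.reshape(tuple(config.grid_shape)) > 0.5


def simulate_study(config: PhantomConfig) -> SyntheticStudy:
    """Full synthetic study: truth, calibration, dynamic series, uptake, masks."""
    config.validate()
    truth = generate_parameter_fields(config)
    aif = config.aif()
    dce = simulate_dce(truth, aif, config)
    t1_vols = simulate_t1_calibration(truth, config)
    spect, spect_aff = simulate_spect(truth, config)
    return SyntheticStudy(
        dce=dce,
        t1_volumes=t1_vols,
        t1_trs_ms=tuple(config.t1_trs_ms),
        spect=spect,
        spect_affine=spect_aff,
        ct_tumor_mask=_mask_in_ct_frame(truth.tumor_mask, config),
        ct_vessel_mask=_mask_in_ct_frame(truth.vessel_mask, config),
        ct_affine=config.affine.copy(),
        applied_transform=config.applied_transform(),
        ground_truth=truth,
        config=config,
    )


def peak_enhancement(config: PhantomConfig) -> float:
    """Robust (98th pct) noiseless peak signal enhancement inside the tumor."""
    truth = generate_parameter_fields(config)
    times = config.times_s()
    sel = truth.tumor_mask
    conc = tofts_forward(truth.ktrans_map[sel], truth.kep_map[sel],
                         config.aif(), times)
    t10 = truth.t10_map[sel][:, None]
    sig = spgr_signal(conc, t10, config.r1_relaxivity, config.tr_dce_ms,
                      config.flip_angle_deg, config.s_scale)
    base = spgr_signal(0.0, truth.t10_map[sel], config.r1_relaxivity,
                       config.tr_dce_ms, config.flip_angle_deg, config.s_scale)
    enh = sig - base[:, None]
    return float(np.percentile(enh.max(axis=1), 98))


def noise_sd_for_snr(config: PhantomConfig, snr: float) -> float:
    """Signal noise SD giving the requested peak-enhancement-to-noise ratio."""
    return peak_enhancement(config) / snr
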