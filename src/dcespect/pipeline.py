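"""End-to-end orchestration: study -> parameter maps -> registration ->
voxel table -> correlation report.

The analysis frame is the fixed (SPECT/CT) grid: the uptake volume is
resampled onto it, the MRI tumor mask is registered to the CT tumor mask, and
every DCE-derived map is transformed with the recovered registration before
correlation. Semi-quantitative maps are min-max normalized per dataset over
the analysis voxels; rate maps stay in absolute units (1/s).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import correlation, pk_model, registration, relaxometry, semiquant
from .correlation import SPECT_COLUMN
from .phantom import SyntheticStudy

__all__ = ["AnalysisOptions", "AnalysisResult", "analyze_study", "make_report",
           "PK_PARAMS", "ALL_PARAMS"]

PK_PARAMS = ("ktrans", "kep")
ALL_PARAMS = semiquant.FEATURE_NAMES + PK_PARAMS

# Parameters that must be defined for a voxel to enter the analysis table.
# wash_in / wash_out may be legitimately undefined (flat curve, peak on the
# last frame) and are carried as flagged NaNs instead.
CORE_PARAMS = ("smax", "ttp", "auc", "auc60")


@dataclass
class AnalysisOptions:
    baseline_frames: int | None = None  # None: infer from study arrival metadata
    gate_threshold_frac: float = 0.1
    r1: float | None = None  # None: take from the study config
    feature_smooth: int = 5  # moving-average window for curve features
    gate_smooth: int = 7  # wider window for the noise-robust gate statistic
    decile_mode: str = "rank"


@dataclass
class AnalysisResult:
    dataset_id: str
    table: pd.DataFrame
    maps_fixed: dict
    maps_mri: dict
    spect_fixed: np.ndarray
    analysis_mask: np.ndarray
    transform: registration.AffineTransform | None
    registration_dice: float | None
    aif: pk_model.AifModel | None
    t10: relaxometry.T10Map | None
    gated_mask: np.ndarray | None
    rho: dict = field(default_factory=dict)
    deciles: dict = field(default_factory=dict)
    params: tuple = ()
    notes: list = field(default_factory=list)


def _full_map(values, index, shape):
    out = np.full(shape, np.nan)
    out[tuple(index.T)] = values
    return out


def analyze_study(study: SyntheticStudy, options: AnalysisOptions | None = None,
                  dataset_id: str = "study") -> AnalysisResult:
    """Run the complete single-dataset analysis.

    If the study carries no T1 calibration stack the pharmacokinetic branch is
    skipped (semi-quantitative-only degraded mode) and a note is recorded.
    """
    opt = options or AnalysisOptions()
    notes: list = []
    times = study.dce.times_s
    cfg = study.config
    truth = study.ground_truth
    shape = study.dce.data.shape[:3]

    if opt.baseline_frames is not None:
        bf = opt.baseline_frames
    elif cfg is not None:
        bf = int(np.sum(times < cfg.arrival_s))
    else:
        bf = 5
    r1 = opt.r1 if opt.r1 is not None else (cfg.r1_relaxivity if cfg else 4.5)

    tumor = truth.tumor_mask
    artery = truth.artery_mask
    t_idx = np.argwhere(tumor)
    curves = study.dce.data[tumor]  # (V, nt)

    # ---- semi-quantitative features (signal space) ----------------------
    feat_curves = semiquant.smooth_curves(curves, opt.feature_smooth)
    feats = semiquant.compute_feature_maps(feat_curves, times, bf)
    maps_mri = {k: _full_map(v, t_idx, shape) for k, v in feats.items()}

    # noise-robust gate statistic: peak of a wider moving average
    gate_curves = semiquant.smooth_curves(curves, opt.gate_smooth)
    base = gate_curves[:, :bf].mean(axis=1, keepdims=True)
    smax_gate = _full_map((gate_curves[:, bf:] - base).max(axis=1), t_idx, shape)

    # ---- pharmacokinetic branch ----------------------------------------
    have_calib = bool(study.t1_volumes)
    aif = None
    t10map = None
    gated_full = None
    if have_calib:
        t10map = relaxometry.fit_t10(study.t1_volumes, study.t1_trs_ms)
        t1_used = np.where(t10map.fit_ok, t10map.t1_ms,
                           np.nanmedian(t10map.t1_ms[tumor]))
        flip, tr_dce = ((cfg.flip_angle_deg, cfg.tr_dce_ms) if cfg else (10.0, 3.4))

        conc_art = relaxometry.signal_to_concentration(
            study.dce.data[artery], t1_used[artery], r1, tr_dce, flip, bf)
        aif = pk_model.fit_aif(conc_art, times)

        conc_tum = relaxometry.signal_to_concentration(
            curves, t1_used[tumor], r1, tr_dce, flip, bf)
        kt, kep, _rss = pk_model.fit_tofts_map(conc_tum, aif, times)
        kt_map = _full_map(kt, t_idx, shape)
        kep_map = _full_map(kep, t_idx, shape)
        kt_map, kep_map, gated_full = pk_model.apply_enhancement_gate(
            kt_map, kep_map, smax_gate, tumor, opt.gate_threshold_frac)
        maps_mri["ktrans"] = kt_map
        maps_mri["kep"] = kep_map
        params = ALL_PARAMS
    else:
        notes.append("no T1 calibration: semi-quantitative-only mode, "
                     "pharmacokinetic maps omitted")
        params = semiquant.FEATURE_NAMES

    # ---- registration + resampling onto the fixed grid ------------------
    mri_aff = study.dce.affine
    transform = registration.register_masks(
        tumor, study.ct_tumor_mask, mri_aff, study.ct_affine)
    moved = registration.resample_map(
        tumor.astype(float), mri_aff, transform, study.ct_tumor_mask.shape,
        study.ct_affine, order=0)
    reg_dice = registration.dice(moved > 0.5, study.ct_tumor_mask)

    maps_fixed = {
        k: registration.resample_map(v, mri_aff, transform,
                                     study.ct_tumor_mask.shape, study.ct_affine,
                                     order=1)
        for k, v in maps_mri.items()
    }
    spect_fixed = registration.resample_map(
        study.spect, study.spect_affine, registration.AffineTransform.identity(),
        study.ct_tumor_mask.shape, study.ct_affine, order=1)

    # ---- analysis mask & per-dataset normalization -----------------------
    mask = study.ct_tumor_mask & ~study.ct_vessel_mask & np.isfinite(spect_fixed)
    for name in CORE_PARAMS + (PK_PARAMS if have_calib else ()):
        mask &= np.isfinite(maps_fixed[name])
    for name in semiquant.FEATURE_NAMES:
        maps_fixed[name] = semiquant.normalize_map(maps_fixed[name], mask, name)

    table = correlation.build_voxel_table(
        spect_fixed, {k: maps_fixed[k] for k in params}, mask, dataset_id)

    rho = {}
    deciles = {}
    for name in params:
        rho[name] = correlation.spearman(table, name)
        deciles[name] = {
            "spect_binned": correlation.decile_summary(
                table, SPECT_COLUMN, name, mode=opt.decile_mode),
            "dce_binned": correlation.decile_summary(
                table, name, SPECT_COLUMN, mode=opt.decile_mode),
        }

    return AnalysisResult(
        dataset_id=dataset_id, table=table, maps_fixed=maps_fixed,
        maps_mri=maps_mri, spect_fixed=spect_fixed, analysis_mask=mask,
        transform=transform, registration_dice=reg_dice, aif=aif, t10=t10map,
        gated_mask=gated_full, rho=rho, deciles=deciles, params=params,
        notes=notes,
    )


def make_report(results) -> dict:
    """Cross-dataset summary: mean/SD Spearman rho and pooled regression.

    The time-to-peak enters the statistics un-inverted, so its rho is
    expected negative; ``abs_rho`` is reported alongside for comparability
    with conventions that invert it.
    """
    results = list(results)
    params = results[0].params
    report = {"datasets": [r.dataset_id for r in results], "parameters": {}}
    tables = [r.table for r in results]
    for name in params:
        rhos = np.array([r.rho[name][0] for r in results])
        pvals = [r.rho[name][1] for r in results]
        entry = {
            "rho_per_dataset": rhos.tolist(),
            "p_per_dataset": pvals,
            "rho_mean": float(rhos.mean()),
            "rho_sd": float(rhos.std(ddof=1)) if len(rhos) > 1 else 0.0,
            "abs_rho_mean": float(np.abs(rhos).mean()),
        }
        if len(results) >= 2:
            slope, intercept, r2, p = correlation.pooled_regression(tables, name)
            entry["pooled"] = {"slope": slope, "intercept": intercept,
                               "r_squared": r2, "p_value": p}
        report["parameters"][name] = entry
    notes = [n for r in results for n in r.notes]
    if notes:
        report["notes"] = notes
    return report
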