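"""Disk layout for studies and analysis runs (NIfTI + JSON/CSV sidecars)."""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import TimedVolumeSeries
from .phantom import GroundTruth, PhantomConfig, SyntheticStudy
from .registration import AffineTransform

__all__ = ["write_study", "load_study", "write_analysis", "config_manifest"]


def _save(path: Path, data, affine) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def _load(path: Path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


def config_manifest(config: PhantomConfig) -> dict:
    blob = json.dumps(config.to_dict(), sort_keys=True)
    return {
        "config": config.to_dict(),
        "seed": config.seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }


def write_study(study: SyntheticStudy, outdir) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    aff = study.dce.affine
    _save(out / "dce.nii.gz", study.dce.data, aff)
    for tr, vol in zip(study.t1_trs_ms, study.t1_volumes):
        _save(out / f"t1_tr{int(tr)}.nii.gz", vol, aff)
    _save(out / "spect.nii.gz", study.spect, study.spect_affine)
    truth = study.ground_truth
    for name in ("tumor_mask", "vessel_mask", "artery_mask", "septa_mask"):
        _save(out / f"{name}.nii.gz", getattr(truth, name).astype(np.float64), aff)
    _save(out / "ct_tumor_mask.nii.gz", study.ct_tumor_mask.astype(np.float64),
          study.ct_affine)
    _save(out / "ct_vessel_mask.nii.gz", study.ct_vessel_mask.astype(np.float64),
          study.ct_affine)
    for name in ("ktrans_map", "kep_map", "ve_map", "t10_map", "receptor_map",
                 "spect_truth", "delivery"):
        _save(out / f"truth_{name}.nii.gz", getattr(truth, name), aff)
    sidecar = {
        "times_s": study.dce.times_s.tolist(),
        "t1_trs_ms": list(study.t1_trs_ms),
        "applied_transform": json.loads(study.applied_transform.to_json()),
        "manifest": config_manifest(study.config) if study.config else None,
    }
    (out / "study.json").write_text(json.dumps(sidecar, indent=2))
    return out


def load_study(indir) -> SyntheticStudy:
    src = Path(indir)
    sidecar = json.loads((src / "study.json").read_text())
    dce_data, aff = _load(src / "dce.nii.gz")
    dce = TimedVolumeSeries(dce_data, np.asarray(sidecar["times_s"]), affine=aff)
    trs = sidecar["t1_trs_ms"]
    t1_vols = [_load(src / f"t1_tr{int(tr)}.nii.gz")[0] for tr in trs]
    spect, spect_aff = _load(src / "spect.nii.gz")
    masks = {}
    for name in ("tumor_mask", "vessel_mask", "artery_mask", "septa_mask"):
        masks[name] = _load(src / f"{name}.nii.gz")[0] > 0.5
    ct_tumor, ct_aff = _load(src / "ct_tumor_mask.nii.gz")
    ct_vessel, _ = _load(src / "ct_vessel_mask.nii.gz")
    truth_fields = {}
    for name in ("ktrans_map", "kep_map", "ve_map", "t10_map", "receptor_map",
                 "spect_truth", "delivery"):
        truth_fields[name] = _load(src / f"truth_{name}.nii.gz")[0]
    truth = GroundTruth(**truth_fields, **masks)
    transform = AffineTransform.from_json(
        json.dumps(sidecar["applied_transform"]))
    manifest = sidecar.get("manifest")
    config = PhantomConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in manifest["config"].items()
    }) if manifest else None
    return SyntheticStudy(
        dce=dce, t1_volumes=t1_vols, t1_trs_ms=tuple(trs), spect=spect,
        spect_affine=spect_aff, ct_tumor_mask=ct_tumor > 0.5,
        ct_vessel_mask=ct_vessel > 0.5, ct_affine=ct_aff,
        applied_transform=transform, ground_truth=truth, config=config,
    )


def write_analysis(result, outdir) -> Path:
    """Persist one dataset's analysis: maps, table, transform, AIF, summaries."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    aff = np.eye(4)
    for name, arr in result.maps_fixed.items():
        _save(out / f"{name}_fixed.nii.gz", arr, aff)
    _save(out / "spect_fixed.nii.gz", result.spect_fixed, aff)
    _save(out / "analysis_mask.nii.gz", result.analysis_mask.astype(np.float64), aff)
    result.table.to_csv(out / "voxel_table.csv", index=False)
    if result.transform is not None:
        (out / "transform.json").write_text(result.transform.to_json())
    if result.aif is not None:
        (out / "aif.json").write_text(json.dumps(result.aif.to_dict(), indent=2))
    summary = {
        "dataset_id": result.dataset_id,
        "registration_dice": result.registration_dice,
        "spearman": {k: {"rho": v[0], "p": v[1]} for k, v in result.rho.items()},
        "notes": result.notes,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    for name, d in result.deciles.items():
        d["spect_binned"].to_csv(out / f"deciles_spect_binned_{name}.csv", index=False)
        d["dce_binned"].to_csv(out / f"deciles_dce_binned_{name}.csv", index=False)
    return out


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not serializable: {type(o)}")
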