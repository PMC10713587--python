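"""NIfTI + JSON-sidecar I/O for dynamic series, maps and reports.

Images travel as NIfTI (affine = diag(spacing)); per-frame timestamps go in
a JSON sidecar ``{"frame_times_s": [...]}`` because NIfTI has no flexible
native per-frame timing field.  Masks are uint8 NIfTI.  All round trips are
lossless (float64 image data, exact timestamps).
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import nibabel as nib
import numpy as np

from .deconv import PerfusionMaps
from .series import DynamicSeries

__all__ = [
    "save_series",
    "load_series",
    "save_maps",
    "load_maps",
    "save_lesion_report",
    "write_provenance",
]


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def _save_nifti(data: np.ndarray, spacing, path: Path, dtype=np.float64) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), _affine(spacing))
    nib.save(img, str(path))


def save_series(s: DynamicSeries, base: str | Path) -> None:
    """Write a series as ``<base>.nii.gz`` + sidecar + optional masks."""
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    _save_nifti(s.frames, s.spacing, base.with_suffix(".nii.gz"))
    sidecar = {
        "frame_times_s": [float(t) for t in s.times],
        "spacing_mm": [float(v) for v in s.spacing],
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    if s.brain_mask is not None:
        _save_nifti(
            s.brain_mask, s.spacing,
            base.parent / f"{base.name}_brainmask.nii.gz", dtype=np.uint8,
        )
    if s.hemisphere_labels is not None:
        _save_nifti(
            s.hemisphere_labels, s.spacing,
            base.parent / f"{base.name}_hemi.nii.gz", dtype=np.uint8,
        )


def load_series(base: str | Path) -> DynamicSeries:
    base = Path(base)
    img = nib.load(str(base.with_suffix(".nii.gz")))
    frames = np.asarray(img.dataobj, dtype=np.float64)
    sidecar = json.loads(base.with_suffix(".json").read_text())
    times = np.asarray(sidecar["frame_times_s"], dtype=float)
    spacing = tuple(sidecar["spacing_mm"])
    mask_path = base.parent / f"{base.name}_brainmask.nii.gz"
    hemi_path = base.parent / f"{base.name}_hemi.nii.gz"
    brain = (
        np.asarray(nib.load(str(mask_path)).dataobj).astype(bool)
        if mask_path.exists()
        else None
    )
    hemi = (
        np.asarray(nib.load(str(hemi_path)).dataobj).astype(np.int8)
        if hemi_path.exists()
        else None
    )
    return DynamicSeries(
        frames=frames, times=times, spacing=spacing,
        brain_mask=brain, hemisphere_labels=hemi,
    )


_MAP_NAMES = ("cbf", "cbv", "mtt", "tmax", "t0", "fit_error")


def save_maps(maps: PerfusionMaps, out_dir: str | Path, extra: dict | None = None) -> None:
    """Write one NIfTI per parameter plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in _MAP_NAMES:
        _save_nifti(getattr(maps, name), maps.spacing, out / f"{name}.nii.gz")
    _save_nifti(maps.valid_mask, maps.spacing, out / "valid_mask.nii.gz",
                dtype=np.uint8)
    manifest = {
        "spacing_mm": [float(v) for v in maps.spacing],
        "t_end_s": float(maps.t_end),
        "units": {
            "cbf": "HU-tissue per HU-artery per second",
            "cbv": "dimensionless fraction",
            "mtt": "s",
            "tmax": "s",
            "t0": "s",
        },
    }
    if extra:
        manifest.update(extra)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_maps(out_dir: str | Path) -> PerfusionMaps:
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    arrays = {
        name: np.asarray(nib.load(str(out / f"{name}.nii.gz")).dataobj,
                         dtype=np.float64)
        for name in _MAP_NAMES
    }
    valid = np.asarray(
        nib.load(str(out / "valid_mask.nii.gz")).dataobj
    ).astype(bool)
    return PerfusionMaps(
        cbf=arrays["cbf"], cbv=arrays["cbv"], mtt=arrays["mtt"],
        tmax=arrays["tmax"], t0=arrays["t0"], fit_error=arrays["fit_error"],
        valid_mask=valid, spacing=tuple(manifest["spacing_mm"]),
        t_end=manifest["t_end_s"],
    )


def save_lesion_report(result, thresholds, criteria, path: str | Path) -> None:
    report = {
        "core_ml": round(result.core_ml, 3),
        "penumbra_ml": round(result.penumbra_ml, 3),
        "mismatch_ratio": (
            None if not np.isfinite(result.mismatch_ratio)
            else round(result.mismatch_ratio, 3)
        ),
        "mismatch_ratio_is_infinite": bool(np.isposinf(result.mismatch_ratio)),
        "profile": result.profile,
        "ipsilateral": result.ipsilateral,
        "thresholds": {
            "rcbf_core_pct": thresholds.rcbf_core_pct,
            "tmax_penumbra_s": thresholds.tmax_penumbra_s,
            "tmax_hypoperfusion_s": thresholds.tmax_hypoperfusion_s,
            "min_component_ml": thresholds.min_component_ml,
        },
        "criteria": {
            "core_max_ml": criteria.core_max_ml,
            "penumbra_min_ml": criteria.penumbra_min_ml,
            "ratio_min": criteria.ratio_min,
        },
    }
    Path(path).write_text(json.dumps(report, indent=2))


def write_provenance(out_dir: str | Path, config: dict, seed: int | None) -> Path:
    """Write a provenance log (config hash, seed, versions)."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    canonical = json.dumps(config, sort_keys=True, default=str)
    log = {
        "config": config,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "sparsectp": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    path = out / "provenance.json"
    path.write_text(json.dumps(log, indent=2, default=str))
    return path
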