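"""Ischemic core / penumbra segmentation and DEFUSE-3 mismatch classification.

Lesion determination is restricted to the ipsilateral hemisphere and to
hypoperfused tissue (Tmax > 4 s).  Ischemic core is relative CBF strictly
below a percent-of-contralateral threshold (15% for CTP, 25% for the sparse
4-frame studies); penumbra is Tmax strictly above a threshold (6 s for CTP,
5 s for the sparse studies), excluding core.  Masks are morphologically
post-processed (closing, opening, per-slice hole filling) and connected
components smaller than 1 ml are discarded.  A favourable target-mismatch
profile requires core < 70 ml, penumbra >= 15 ml and penumbra/core >= 1.8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .deconv import PerfusionMaps, relative_cbf
from .series import HEMI_LEFT, HEMI_RIGHT, DynamicSeries

__all__ = [
    "LesionThresholds",
    "MismatchCriteria",
    "LesionResult",
    "CTP_THRESHOLDS",
    "SPARSE_THRESHOLDS",
    "DEFUSE3_CRITERIA",
    "hypoperfusion_mask",
    "segment_core",
    "segment_penumbra",
    "postprocess_mask",
    "mask_volume_ml",
    "classify_mismatch",
    "analyze_lesions",
]


@dataclass(frozen=True)
class LesionThresholds:
    """Segmentation thresholds for one study type."""

    rcbf_core_pct: float
    tmax_penumbra_s: float
    tmax_hypoperfusion_s: float = 4.0
    min_component_ml: float = 1.0

    def __post_init__(self) -> None:
        vals = (
            self.rcbf_core_pct,
            self.tmax_penumbra_s,
            self.tmax_hypoperfusion_s,
            self.min_component_ml,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all thresholds must be positive")
        if self.tmax_penumbra_s <= self.tmax_hypoperfusion_s:
            raise ValueError(
                "the penumbra Tmax threshold must exceed the hypoperfusion gate"
            )


@dataclass(frozen=True)
class MismatchCriteria:
    """DEFUSE-3 target-mismatch profile criteria."""

    core_max_ml: float = 70.0
    penumbra_min_ml: float = 15.0
    ratio_min: float = 1.8

    def __post_init__(self) -> None:
        if min(self.core_max_ml, self.penumbra_min_ml, self.ratio_min) <= 0:
            raise ValueError("mismatch criteria must be positive")


#: Optimal thresholds for densely sampled CTP.
CTP_THRESHOLDS = LesionThresholds(rcbf_core_pct=15.0, tmax_penumbra_s=6.0)
#: Optimal thresholds for the 4-frame studies (dCTP and mCTA-P).
SPARSE_THRESHOLDS = LesionThresholds(rcbf_core_pct=25.0, tmax_penumbra_s=5.0)
DEFUSE3_CRITERIA = MismatchCriteria()


@dataclass
class LesionResult:
    """Lesion masks, volumes and the mismatch profile."""

    hypoperfusion_mask: np.ndarray
    core_mask: np.ndarray
    penumbra_mask: np.ndarray
    core_ml: float
    penumbra_ml: float
    mismatch_ratio: float
    profile: str
    ipsilateral: str


def hypoperfusion_mask(
    maps: PerfusionMaps,
    ipsilateral_mask: np.ndarray,
    thresholds: LesionThresholds,
) -> np.ndarray:
    """Ipsilateral valid voxels with Tmax strictly above the 4 s gate."""
    return (
        np.asarray(ipsilateral_mask, bool)
        & maps.valid_mask
        & (maps.tmax > thresholds.tmax_hypoperfusion_s)
    )


def segment_core(
    rcbf_map: np.ndarray,
    thresholds: LesionThresholds,
    hypo_mask: np.ndarray,
) -> np.ndarray:
    """Hypoperfused voxels with relative CBF strictly below the threshold."""
    return hypo_mask & (rcbf_map < thresholds.rcbf_core_pct)


def segment_penumbra(
    maps: PerfusionMaps,
    thresholds: LesionThresholds,
    hypo_mask: np.ndarray,
    core_mask: np.ndarray,
) -> np.ndarray:
    """Hypoperfused voxels with Tmax above the threshold, excluding core."""
    return hypo_mask & (maps.tmax > thresholds.tmax_penumbra_s) & ~core_mask


def _ellipsoid_element(radius_mm: float, spacing) -> np.ndarray:
    """Spherical structuring element scaled anisotropically to voxels."""
    half = [max(int(np.floor(radius_mm / s + 1e-9)), 0) for s in spacing]
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, spacing)],
        indexing="ij",
    )
    r2 = sum(g * g for g in grids)
    return r2 <= radius_mm**2 + 1e-9


def postprocess_mask(
    mask: np.ndarray,
    spacing,
    min_component_ml: float = 1.0,
    radius_mm: float = 2.0,
) -> np.ndarray:
    """Morphological cleanup of a binary lesion mask.

    Binary closing, then opening (2 mm spherical element scaled to voxel
    spacing), per-slice hole filling, then removal of 26-connected components
    with volume below ``min_component_ml``.
    """
    mask = np.asarray(mask, bool)
    selem = _ellipsoid_element(radius_mm, spacing)
    out = ndimage.binary_closing(mask, structure=selem)
    out = ndimage.binary_opening(out, structure=selem)
    for k in range(out.shape[2]):
        out[:, :, k] = ndimage.binary_fill_holes(out[:, :, k])
    labels, n = ndimage.label(out, structure=np.ones((3, 3, 3), dtype=int))
    if n:
        voxel_ml = float(np.prod(spacing)) / 1000.0
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts * voxel_ml < min_component_ml)
        small = small[small > 0]
        if small.size:
            out &= ~np.isin(labels, small)
    return out


def mask_volume_ml(mask: np.ndarray, spacing) -> float:
    """Volume of a binary mask in millilitres."""
    voxel_mm3 = float(np.prod(spacing))
    return float(np.count_nonzero(mask)) * voxel_mm3 / 1000.0


def classify_mismatch(
    core_ml: float,
    penumbra_ml: float,
    criteria: MismatchCriteria = DEFUSE3_CRITERIA,
):
    """Mismatch ratio (penumbra / core) and target-mismatch profile.

    Returns ``(ratio, profile)`` with profile in {'favourable',
    'unfavourable'}.  A zero core with non-zero penumbra gives an infinite
    ratio (which satisfies the ratio criterion); two zero volumes give an
    undefined (NaN) ratio and an unfavourable profile.
    """
    if core_ml < 0 or penumbra_ml < 0:
        raise ValueError("lesion volumes must be non-negative")
    if core_ml == 0:
        ratio = np.inf if penumbra_ml > 0 else np.nan
    else:
        ratio = penumbra_ml / core_ml
    favourable = (
        core_ml < criteria.core_max_ml
        and penumbra_ml >= criteria.penumbra_min_ml
        and (np.isfinite(ratio) or np.isposinf(ratio))
        and ratio >= criteria.ratio_min
    )
    return float(ratio), ("favourable" if favourable else "unfavourable")


def _auto_side(maps: PerfusionMaps, labels: np.ndarray, gate_s: float) -> str:
    left = np.count_nonzero(
        maps.valid_mask & (labels == HEMI_LEFT) & (maps.tmax > gate_s)
    )
    right = np.count_nonzero(
        maps.valid_mask & (labels == HEMI_RIGHT) & (maps.tmax > gate_s)
    )
    return "left" if left >= right else "right"


def analyze_lesions(
    maps: PerfusionMaps,
    s: DynamicSeries,
    thresholds: LesionThresholds = CTP_THRESHOLDS,
    criteria: MismatchCriteria = DEFUSE3_CRITERIA,
    ipsilateral: str | None = None,
    postprocess: bool = True,
) -> LesionResult:
    """Full lesion analysis: masks, volumes, mismatch ratio and profile.

    If ``ipsilateral`` is None the side with the larger Tmax > 4 s volume is
    chosen automatically.  The morphological post-processing is applied to
    the hypoperfusion, core and penumbra masks; core and penumbra are kept
    nested inside the processed hypoperfusion mask and mutually disjoint.
    """
    if s.hemisphere_labels is None:
        raise ValueError("hemisphere labels are required for lesion analysis")
    labels = s.hemisphere_labels
    if ipsilateral is None:
        ipsilateral = _auto_side(maps, labels, thresholds.tmax_hypoperfusion_s)
    code = HEMI_LEFT if ipsilateral == "left" else HEMI_RIGHT
    ipsi = labels == code

    rcbf = relative_cbf(maps, s, ipsilateral)
    hypo = hypoperfusion_mask(maps, ipsi, thresholds)
    core = segment_core(rcbf, thresholds, hypo)
    pen = segment_penumbra(maps, thresholds, hypo, core)
    if postprocess:
        spacing = maps.spacing
        hypo = postprocess_mask(hypo, spacing, thresholds.min_component_ml)
        core = postprocess_mask(core, spacing, thresholds.min_component_ml) & hypo
        pen = postprocess_mask(pen, spacing, thresholds.min_component_ml) & hypo
    pen = pen & ~core

    core_ml = mask_volume_ml(core, maps.spacing)
    pen_ml = mask_volume_ml(pen, maps.spacing)
    ratio, profile = classify_mismatch(core_ml, pen_ml, criteria)
    return LesionResult(
        hypoperfusion_mask=hypo,
        core_mask=core,
        penumbra_mask=pen,
        core_ml=core_ml,
        penumbra_ml=pen_ml,
        mismatch_ratio=ratio,
        profile=profile,
        ipsilateral=ipsilateral,
    )
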