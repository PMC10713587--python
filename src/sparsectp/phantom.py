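"""Digital phantoms with known ground truth.

Two generators make every pipeline stage testable without clinical data:

* a 4-D digital brain with spatially varying JWL parameters (an ellipsoidal
  brain, a lesion of reduced flow and increased delay in one hemisphere,
  artery- and vein-like voxels, a gamma-variate arterial input, Gaussian
  noise, and the CTP or mCTA-P sampling scheme with its additive HU bias);
* a static head phantom (skull annulus around a plexiglass-like interior)
  for the CT-number ring analysis used to estimate the NCCT-to-mCTA bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import ndimage

from .deconv import PerfusionMaps
from .kinetics import GammaVariate, KineticParams, TimeDensityCurve, tissue_forward
from .series import (
    HEMI_LEFT,
    HEMI_NONE,
    HEMI_RIGHT,
    AcquisitionProtocol,
    DynamicSeries,
    VesselCurves,
)

__all__ = [
    "GammaVariate",
    "LesionRegion",
    "DigitalBrainSpec",
    "HeadPhantomSpec",
    "RingStat",
    "RingProfile",
    "BiasEstimate",
    "generate_digital_brain",
    "generate_head_phantom",
    "ring_ct_numbers",
    "estimate_bias",
]


@dataclass(frozen=True)
class LesionRegion:
    """An ellipsoidal region with its own kinetic parameters."""

    center_mm: tuple
    radii_mm: tuple
    params: KineticParams


def _default_lesions() -> tuple:
    # outer penumbra-like shell: 40% of normal flow, Tmax = 4 + 6/2 = 7 s;
    # inner core: 12% of normal flow, Tmax = 5 + 8/2 = 9 s
    return (
        LesionRegion(
            center_mm=(24.0, 0.0, 0.0),
            radii_mm=(20.0, 20.0, 14.0),
            params=KineticParams(t0=4.0, w=6.0, f=0.004, e=0.0),
        ),
        LesionRegion(
            center_mm=(24.0, 0.0, 0.0),
            radii_mm=(9.0, 9.0, 8.0),
            params=KineticParams(t0=5.0, w=8.0, f=0.0012, e=0.0),
        ),
    )


@dataclass
class DigitalBrainSpec:
    """Ground-truth description of the digital dynamic brain.

    Defaults give a 64 x 64 x 8 grid at 2 x 2 x 5 mm so that a full
    pipeline run completes in seconds.  Normal tissue has Tmax = 3 s
    (below the 4 s hypoperfusion gate); the right-hemisphere lesion has an
    outer shell above the penumbra thresholds and an inner core below the
    relative-CBF core thresholds.  Noise is additive Gaussian in HU, and the
    arterial input peaks at 16 s, matching the fixed NCCT-to-first-phase
    interval of the mCTA-P protocol.
    """

    shape: tuple = (64, 64, 8)
    spacing: tuple = (2.0, 2.0, 5.0)
    brain_radii_mm: tuple = (56.0, 56.0, 18.0)
    normal: KineticParams = field(
        default_factory=lambda: KineticParams(t0=1.0, w=4.0, f=0.01, e=0.0)
    )
    lesions: tuple = field(default_factory=_default_lesions)
    aif: GammaVariate = field(default_factory=GammaVariate)
    vof: GammaVariate = field(
        default_factory=lambda: GammaVariate(
            peak_hu=260.0, onset_s=9.0, alpha=3.0, scale_s=4.0
        )
    )
    aif_center_mm: tuple = (-24.0, 0.0, 0.0)
    vof_center_mm: tuple = (-4.0, 30.0, 0.0)
    baseline_hu: float = 35.0
    vessel_baseline_hu: float = 45.0
    noise_sd: float = 2.0
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_spec_to_dict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DigitalBrainSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return _spec_from_dict(raw)


def _spec_to_dict(spec: DigitalBrainSpec) -> dict:
    d = asdict(spec)
    d["normal"] = asdict(spec.normal)
    d["lesions"] = [
        {
            "center_mm": list(r.center_mm),
            "radii_mm": list(r.radii_mm),
            "params": asdict(r.params),
        }
        for r in spec.lesions
    ]
    d["aif"] = asdict(spec.aif)
    d["vof"] = asdict(spec.vof)
    for key in ("shape", "spacing", "brain_radii_mm", "aif_center_mm",
                "vof_center_mm"):
        d[key] = list(d[key])
    return d


def _spec_from_dict(raw: dict) -> DigitalBrainSpec:
    lesions = tuple(
        LesionRegion(
            center_mm=tuple(r["center_mm"]),
            radii_mm=tuple(r["radii_mm"]),
            params=KineticParams(**r["params"]),
        )
        for r in raw.get("lesions", [])
    )
    kwargs = dict(raw)
    kwargs["normal"] = KineticParams(**raw["normal"])
    kwargs["lesions"] = lesions
    kwargs["aif"] = GammaVariate(**raw["aif"])
    kwargs["vof"] = GammaVariate(**raw["vof"])
    for key in ("shape", "spacing", "brain_radii_mm", "aif_center_mm",
                "vof_center_mm"):
        kwargs[key] = tuple(raw[key])
    return DigitalBrainSpec(**kwargs)


def _grid_mm(shape, spacing):
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_mask(coords, center, radii):
    q = sum(
        ((c - c0) / r) ** 2 for c, c0, r in zip(coords, center, radii)
    )
    return q <= 1.0


def generate_digital_brain(
    spec: DigitalBrainSpec, protocol: AcquisitionProtocol
):
    """Generate a dynamic series plus its ground truth.

    Returns ``(series, truth_maps, truth_vessels)``.  Voxel curves are the
    JWL forward model driven by the gamma-variate AIF, sampled at the
    protocol's frame times, on top of the tissue baseline HU, with i.i.d.
    Gaussian noise.  Under the mCTA-P protocol the protocol's ``bias_hu`` is
    added to brain voxels of the post-baseline frames (emulating the scatter
    shift of the wider mCTA collimation).  Ground-truth maps are derived in
    closed form with the scan span as the integration window; artery/vein
    voxels are excluded from the truth validity mask.
    """
    times = np.asarray(protocol.frame_times, float)
    coords = _grid_mm(spec.shape, spec.spacing)
    brain = _ellipsoid_mask(coords, (0.0, 0.0, 0.0), spec.brain_radii_mm)
    hemi = np.full(spec.shape, HEMI_NONE, dtype=np.int8)
    hemi[brain & (coords[0] < 0)] = HEMI_LEFT
    hemi[brain & (coords[0] >= 0)] = HEMI_RIGHT

    # piecewise-constant parameter maps
    t0 = np.full(spec.shape, spec.normal.t0)
    w = np.full(spec.shape, spec.normal.w)
    f = np.full(spec.shape, spec.normal.f)
    e = np.full(spec.shape, spec.normal.e)
    for region in spec.lesions:
        rmask = _ellipsoid_mask(coords, region.center_mm, region.radii_mm)
        if not (rmask <= brain).all():
            raise ValueError("lesion region extends outside the brain")
        sides = np.unique(hemi[rmask])
        if len(sides) != 1:
            raise ValueError("lesion region must lie inside one hemisphere")
        t0[rmask] = region.params.t0
        w[rmask] = region.params.w
        f[rmask] = region.params.f
        e[rmask] = region.params.e

    # vessel voxels: artery and vein as 3x3x1 blocks, so the in-plane 3x3
    # neighbourhood of the centre voxel samples the undiluted vessel curve
    def _vessel_mask(center_mm):
        m = np.zeros(spec.shape, dtype=bool)
        idx = [
            int(round(c / s + (n - 1) / 2.0))
            for c, s, n in zip(center_mm, spec.spacing, spec.shape)
        ]
        m[idx[0] - 1 : idx[0] + 2, idx[1] - 1 : idx[1] + 2, idx[2]] = True
        if not (m <= brain).all():
            raise ValueError("vessel location outside the brain")
        return m, tuple(idx)

    aif_mask, aif_loc = _vessel_mask(spec.aif_center_mm)
    vof_mask, vof_loc = _vessel_mask(spec.vof_center_mm)
    vessel = aif_mask | vof_mask

    # forward tissue curves, one per distinct parameter tuple, generated on
    # a fine grid so the sampled curves approximate the continuous response
    dt_gen = 0.1
    t_hi = np.arange(0.0, np.ceil(times[-1]) + 1.0 + dt_gen / 2, dt_gen)
    aif_curve = TimeDensityCurve(t_hi, spec.aif.value(t_hi))
    frames = np.zeros(spec.shape + (len(times),))
    tissue = brain & ~vessel
    combos = np.stack([t0, w, f, e], axis=-1)[tissue]
    uniq, inverse = np.unique(combos, axis=0, return_inverse=True)
    curves = np.empty((len(uniq), len(times)))
    for i, (ct0, cw, cf, ce) in enumerate(uniq):
        params = KineticParams(t0=float(ct0), w=float(cw), f=float(cf), e=float(ce))
        curves[i] = tissue_forward(aif_curve, params, times).values
    frames[tissue] = spec.baseline_hu + curves[inverse]
    frames[aif_mask] = spec.vessel_baseline_hu + spec.aif.value(times)
    frames[vof_mask] = spec.vessel_baseline_hu + spec.vof.value(times)

    if protocol.name == "mcta_p" and protocol.bias_hu:
        for j in range(1, len(times)):
            frame = frames[..., j]
            frame[brain] += protocol.bias_hu

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        frames = frames + rng.normal(0.0, spec.noise_sd, frames.shape)

    series = DynamicSeries(
        frames=frames,
        times=times,
        spacing=spec.spacing,
        brain_mask=brain,
        hemisphere_labels=hemi,
    )

    t_end = float(times[-1] - times[0])
    tail = np.clip(t_end - t0 - w, 0.0, None)
    cbv = f * (w + e * tail)
    with np.errstate(divide="ignore", invalid="ignore"):
        mtt = np.where(f > 0, cbv / np.where(f > 0, f, 1.0), 0.0)
    tmax = t0 + 0.5 * mtt
    valid = tissue
    truth = PerfusionMaps(
        cbf=np.where(valid, f, 0.0),
        cbv=np.where(valid, cbv, 0.0),
        mtt=np.where(valid, mtt, 0.0),
        tmax=np.where(valid, tmax, 0.0),
        t0=np.where(valid, t0, 0.0),
        fit_error=np.zeros(spec.shape),
        valid_mask=valid,
        spacing=spec.spacing,
        t_end=t_end,
    )
    vessels = VesselCurves(
        aif=TimeDensityCurve(times, spec.aif.value(times)),
        vof=TimeDensityCurve(times, spec.vof.value(times)),
        aif_location=aif_loc,
        vof_location=vof_loc,
    )
    return series, truth, vessels


@dataclass
class HeadPhantomSpec:
    """A skull annulus around a plexiglass-like interior, with radial bias."""

    shape: tuple = (128, 128, 2)
    spacing: tuple = (1.5, 1.5, 5.0)
    interior_radius_mm: float = 70.0
    skull_outer_radius_mm: float = 80.0
    skull_hu: float = 1000.0
    interior_hu: float = 150.0
    air_hu: float = -1000.0
    bias_offset_hu: float = 0.0
    bias_slope_hu_per_mm: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 100.0 <= self.interior_hu <= 200.0:
            raise ValueError(
                "interior HU must lie in the [100, 200] segmentation window"
            )

    def bias(self, radius_mm):
        return self.bias_offset_hu + self.bias_slope_hu_per_mm * np.asarray(
            radius_mm, float
        )


@dataclass(frozen=True)
class RingStat:
    inner_mm: float
    outer_mm: float
    mean_hu: float
    n_voxels: int


@dataclass
class RingProfile:
    """Mean CT number in concentric 10 mm rings."""

    rings: list
    ring_width_mm: float = 10.0

    def __len__(self) -> int:
        return len(self.rings)


@dataclass(frozen=True)
class BiasEstimate:
    per_ring_hu: tuple
    pooled_hu: float


def generate_head_phantom(spec: HeadPhantomSpec) -> np.ndarray:
    """Simulated head-phantom scan (3-D HU image), deterministic under seed."""
    x, y, _ = _grid_mm(spec.shape, spec.spacing)
    r = np.hypot(x, y)
    img = np.full(spec.shape, spec.air_hu)
    interior = r < spec.interior_radius_mm
    skull = (r >= spec.interior_radius_mm) & (r < spec.skull_outer_radius_mm)
    img[interior] = spec.interior_hu + spec.bias(r[interior])
    img[skull] = spec.skull_hu
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return img


def _disk_element(radius_mm: float, spacing) -> np.ndarray:
    hx = max(int(np.floor(radius_mm / spacing[0] + 1e-9)), 0)
    hy = max(int(np.floor(radius_mm / spacing[1] + 1e-9)), 0)
    gx, gy = np.meshgrid(
        np.arange(-hx, hx + 1) * spacing[0],
        np.arange(-hy, hy + 1) * spacing[1],
        indexing="ij",
    )
    return (gx**2 + gy**2 <= radius_mm**2 + 1e-9)[:, :, None]


def ring_ct_numbers(
    image: np.ndarray,
    spacing,
    window_hu=(100.0, 200.0),
    erode_mm: float = 5.0,
    ring_width_mm: float = 10.0,
) -> RingProfile:
    """Radial ring analysis of a head-phantom image.

    Thresholds voxels inside the HU window, keeps the largest connected
    component, erodes it by a 5 mm in-plane disk (to mitigate partial-volume
    voxels near the bone), then partitions it into concentric 10 mm rings
    around the per-slice centroid and reports the mean HU per ring.
    """
    seg = (image >= window_hu[0]) & (image <= window_hu[1])
    labels, n = ndimage.label(seg)
    if n == 0:
        raise ValueError("no voxels inside the segmentation window")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    seg = labels == int(np.argmax(counts))
    seg = ndimage.binary_erosion(seg, structure=_disk_element(erode_mm, spacing))
    if not seg.any():
        raise ValueError("segmentation is empty after erosion")

    dist = np.full(image.shape, np.nan)
    for k in range(image.shape[2]):
        sl = seg[:, :, k]
        if not sl.any():
            continue
        ii, jj = np.nonzero(sl)
        ci = ii.mean()
        cj = jj.mean()
        dist[ii, jj, k] = np.hypot(
            (ii - ci) * spacing[0], (jj - cj) * spacing[1]
        )
    d = dist[seg]
    v = image[seg]
    n_rings = int(np.floor(d.max() / ring_width_mm)) + 1
    rings = []
    for k in range(n_rings):
        lo, hi = k * ring_width_mm, (k + 1) * ring_width_mm
        sel = (d >= lo) & (d < hi)
        if not sel.any():
            continue
        rings.append(
            RingStat(
                inner_mm=lo,
                outer_mm=hi,
                mean_hu=float(v[sel].mean()),
                n_voxels=int(sel.sum()),
            )
        )
    return RingProfile(rings=rings, ring_width_mm=ring_width_mm)


def estimate_bias(
    profile_ncct: RingProfile, profile_mcta: RingProfile
) -> BiasEstimate:
    """Per-ring and pooled CT-number offset (mCTA minus NCCT).

    The pooled estimate weights each common ring by its (mean) voxel count.
    Profiles with different ring counts are compared over the common rings
    with a warning.
    """
    import warnings

    n_common = min(len(profile_ncct), len(profile_mcta))
    if len(profile_ncct) != len(profile_mcta):
        warnings.warn(
            "ring-count mismatch between profiles; comparing common rings only",
            stacklevel=2,
        )
    diffs = []
    weights = []
    for a, b in zip(profile_ncct.rings[:n_common], profile_mcta.rings[:n_common]):
        diffs.append(b.mean_hu - a.mean_hu)
        weights.append(0.5 * (a.n_voxels + b.n_voxels))
    pooled = float(np.average(diffs, weights=weights))
    return BiasEstimate(per_ring_hu=tuple(diffs), pooled_hu=pooled)
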