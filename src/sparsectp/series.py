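"""Dynamic CT series container and preprocessing.

Covers the shared plumbing of the three dynamic studies (CTP, down-sampled
CTP, and the NCCT+mCTA "mCTA-P" surrogate): temporal interpolation to a 1 s
virtual grid, in-plane Gaussian smoothing, simplified rigid in-plane motion
correction, automatic arterial/venous input detection, CTP down-sampling to
the 4-frame mCTA timing, mCTA-P assembly with a zeroth-order HU bias
correction, and axial slab averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .kinetics import TimeDensityCurve

__all__ = [
    "HEMI_NONE",
    "HEMI_LEFT",
    "HEMI_RIGHT",
    "DynamicSeries",
    "AcquisitionProtocol",
    "VesselCurves",
    "NoVesselError",
    "interpolate_to_1s",
    "smooth_spatial",
    "apply_inplane_transform",
    "motion_correct_inplane",
    "detect_aif_vof",
    "downsample_ctp",
    "assemble_mcta_p",
    "correct_mcta_bias",
    "slab_average",
]

HEMI_NONE = 0
HEMI_LEFT = 1
HEMI_RIGHT = 2

#: FWHM-to-sigma conversion for a Gaussian: sigma = FWHM / sqrt(8 ln 2)
FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


class NoVesselError(RuntimeError):
    """Raised when no voxel qualifies as a vessel candidate."""


@dataclass
class DynamicSeries:
    """A 4-D dynamic CT study.

    frames
        (nx, ny, nz, nt) array of CT numbers in HU.
    times
        Acquisition time of each frame in seconds, strictly increasing,
        with t = 0 at the first acquired frame of the study's protocol.
    spacing
        Voxel spacing (dx, dy, dz) in mm.
    brain_mask
        Optional (nx, ny, nz) boolean brain mask.
    hemisphere_labels
        Optional (nx, ny, nz) int labels: 0 none, 1 left, 2 right.
    """

    frames: np.ndarray
    times: np.ndarray
    spacing: tuple
    brain_mask: np.ndarray | None = None
    hemisphere_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.frames.ndim != 4:
            raise ValueError("frames must be 4-D (x, y, z, t)")
        if self.frames.shape[3] != len(self.times):
            raise ValueError("number of frames and timestamps must agree")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")
        for name in ("brain_mask", "hemisphere_labels"):
            m = getattr(self, name)
            if m is not None and m.shape != self.frames.shape[:3]:
                raise ValueError(f"{name} shape must match the spatial grid")
        if self.brain_mask is not None:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[3]

    def enhancement(self) -> np.ndarray:
        """Baseline-subtracted frames (first frame is the baseline)."""
        return self.frames - self.frames[..., :1]

    def voxel_curve(self, index) -> TimeDensityCurve:
        i, j, k = index
        return TimeDensityCurve(self.times, self.enhancement()[i, j, k, :])

    def with_frames(self, frames, times) -> "DynamicSeries":
        return DynamicSeries(
            frames=frames,
            times=times,
            spacing=self.spacing,
            brain_mask=self.brain_mask,
            hemisphere_labels=self.hemisphere_labels,
        )


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Frame timing (and HU bias) of a dynamic acquisition."""

    name: str
    frame_times: tuple
    bias_hu: float = 0.0

    @classmethod
    def ctp(cls) -> "AcquisitionProtocol":
        """Standard CTP: 5 s prep, 22 frames at 2.8 s, then 6 at 15 s."""
        fast = 5.0 + 2.8 * np.arange(22)
        slow = fast[-1] + 15.0 * np.arange(1, 7)
        return cls(name="ctp", frame_times=tuple(np.concatenate([fast, slow])))

    @classmethod
    def mcta_p(cls, bias_hu: float = 4.0) -> "AcquisitionProtocol":
        """NCCT baseline then mCTA phases at +16, +24, +32 s.

        ``bias_hu`` is the additive CT-number offset of the mCTA frames
        relative to NCCT (wider beam collimation increases scatter).
        """
        return cls(
            name="mcta_p", frame_times=(0.0, 16.0, 24.0, 32.0), bias_hu=bias_hu
        )


@dataclass
class VesselCurves:
    """Automatically detected arterial and venous input curves."""

    aif: TimeDensityCurve
    vof: TimeDensityCurve
    aif_location: tuple
    vof_location: tuple


def interpolate_to_1s(s: DynamicSeries) -> DynamicSeries:
    """Linearly interpolate a series to a 1 s virtual sampling interval.

    Output times are the integer seconds spanning [min(times), max(times)];
    values at original timestamps that fall on the grid are preserved.
    """
    if s.n_frames < 2:
        raise ValueError("at least 2 frames are required for interpolation")
    t = s.times
    new_times = np.arange(np.ceil(t[0] - 1e-9), np.floor(t[-1] + 1e-9) + 0.5)
    idx = np.clip(np.searchsorted(t, new_times, side="right") - 1, 0, len(t) - 2)
    w = (new_times - t[idx]) / (t[idx + 1] - t[idx])
    w = np.clip(w, 0.0, 1.0)
    frames = s.frames[..., idx] * (1.0 - w) + s.frames[..., idx + 1] * w
    return s.with_frames(frames, new_times)


def smooth_spatial(s: DynamicSeries, fwhm_mm: float = 4.8) -> DynamicSeries:
    """In-plane Gaussian smoothing of each frame.

    ``sigma_mm = fwhm_mm / sqrt(8 ln 2)`` converted to voxels per in-plane
    axis; no smoothing across slices or frames.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    sigma_mm = fwhm_mm * FWHM_TO_SIGMA
    sig = (sigma_mm / s.spacing[0], sigma_mm / s.spacing[1], 0.0, 0.0)
    frames = ndimage.gaussian_filter(s.frames, sigma=sig, mode="nearest")
    return s.with_frames(frames, s.times.copy())


def apply_inplane_transform(
    volume: np.ndarray, dx: float, dy: float, theta_deg: float
) -> np.ndarray:
    """Resample a 3-D volume under an in-plane rigid transform.

    The output at voxel x samples the input at ``R(x - c) + c + (dx, dy)``
    where R rotates by ``theta_deg`` about the in-plane centre c.  Units are
    voxels and degrees.
    """
    th = np.deg2rad(theta_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    c = (np.asarray(volume.shape[:2], dtype=float) - 1.0) / 2.0
    offset = c + np.array([dx, dy]) - rot @ c
    out = np.empty_like(volume, dtype=float)
    for k in range(volume.shape[2]):
        out[:, :, k] = ndimage.affine_transform(
            volume[:, :, k], rot, offset=offset, order=1, mode="nearest"
        )
    return out


def motion_correct_inplane(s: DynamicSeries):
    """Align each frame to the baseline by an in-plane rigid transform.

    A single (dx, dy, theta) transform per frame (shared across slices) is
    estimated by minimising the masked sum of squared differences against the
    first frame, initialised from the integer shift that best explains the
    slice-averaged images.  Returns the corrected series and a per-frame
    transform log.
    """
    if s.brain_mask is None or not s.brain_mask.any():
        raise ValueError("motion correction requires a non-empty brain mask")
    base = s.frames[..., 0]
    mask = s.brain_mask

    def sse(frame, params):
        moved = apply_inplane_transform(frame, *params)
        d = (moved - base)[mask]
        return float(d @ d)

    frames_out = np.empty_like(s.frames)
    frames_out[..., 0] = base
    log = [{"dx_vox": 0.0, "dy_vox": 0.0, "theta_deg": 0.0, "sse": 0.0}]
    base_mean = base.mean(axis=2)
    for j in range(1, s.n_frames):
        frame = s.frames[..., j]
        # coarse translation init via 2-D cross-correlation of slice means
        corr = ndimage.correlate(
            frame.mean(axis=2) - frame.mean(), base_mean - base_mean.mean(),
            mode="constant",
        )
        ci, cj = np.unravel_index(np.argmax(corr), corr.shape)
        guess = (
            ci - (corr.shape[0] - 1) / 2.0,
            cj - (corr.shape[1] - 1) / 2.0,
        )
        inits = [(0.0, 0.0, 0.0), (guess[0], guess[1], 0.0),
                 (-guess[0], -guess[1], 0.0)]
        x0 = min(inits, key=lambda p: sse(frame, p))
        res = optimize.minimize(
            lambda p: sse(frame, p), x0=np.asarray(x0), method="Powell",
            options={"xtol": 1e-3, "ftol": 1e-6},
        )
        dx, dy, th = res.x
        frames_out[..., j] = apply_inplane_transform(frame, dx, dy, th)
        log.append(
            {"dx_vox": float(dx), "dy_vox": float(dy),
             "theta_deg": float(th), "sse": float(res.fun)}
        )
    return s.with_frames(frames_out, s.times.copy()), log


def _neighbourhood_curve(enh, mask, index):
    i, j, k = index
    sl = np.s_[max(i - 1, 0): i + 2, max(j - 1, 0): j + 2, k]
    sub = enh[sl]
    m = mask[sl]
    return sub[m].mean(axis=0)


def detect_aif_vof(
    s: DynamicSeries,
    min_peak_enh: float = 10.0,
    percentile: float = 99.0,
) -> VesselCurves:
    """Automatic arterial and venous input detection.

    Candidates are brain voxels whose peak enhancement exceeds the given
    percentile of peak enhancement inside the mask.  Each candidate's curve
    is averaged over its in-plane 3x3 neighbourhood (within the mask).  The
    AIF is the candidate maximising peak / equivalent-width (tall, early,
    narrow; earlier time-to-peak breaks ties); the VOF is the candidate with
    the largest area under the curve among those peaking no earlier than the
    AIF.
    """
    if s.brain_mask is None or not s.brain_mask.any():
        raise ValueError("vessel detection requires a non-empty brain mask")
    enh = s.enhancement()
    mask = s.brain_mask
    peak = enh.max(axis=3)
    masked_peaks = peak[mask]
    if masked_peaks.max() < min_peak_enh:
        raise NoVesselError(
            "no vessel candidate: no voxel exceeds the minimum enhancement"
        )
    # cap the percentile threshold at half the global maximum so a slightly
    # taller vein cannot crowd the artery out of the candidate set
    thr = max(
        min(float(np.percentile(masked_peaks, percentile)),
            0.5 * float(masked_peaks.max())),
        min_peak_enh,
    )
    cand = np.argwhere(mask & (peak >= thr))
    scores = []
    for idx in cand:
        curve = _neighbourhood_curve(enh, mask, tuple(idx))
        p = float(curve.max())
        pos = np.clip(curve, 0.0, None)
        auc = float(np.trapezoid(pos, s.times))
        if p <= 0 or auc <= 0:
            continue
        ttp = float(s.times[int(np.argmax(curve))])
        # first moment of the curve: bolus centre-of-mass time (earliness)
        m1 = float(np.trapezoid(pos * s.times, s.times)) / auc
        # composite: tall (peak), narrow (equivalent width = auc / peak),
        # early (first moment); larger is more artery-like
        score = p * p / (auc * max(m1, 1e-6))
        scores.append((score, ttp, auc, tuple(int(v) for v in idx), curve))
    if not scores:
        raise NoVesselError("no vessel candidate with positive enhancement")
    # AIF: max composite score, ties broken by earlier time-to-peak
    aif_entry = max(scores, key=lambda e: (e[0], -e[1]))
    aif_ttp = aif_entry[1]
    late = [e for e in scores if e[1] >= aif_ttp]
    vof_entry = max(late, key=lambda e: e[2])
    return VesselCurves(
        aif=TimeDensityCurve(s.times.copy(), aif_entry[4]),
        vof=TimeDensityCurve(s.times.copy(), vof_entry[4]),
        aif_location=aif_entry[3],
        vof_location=vof_entry[3],
    )


def downsample_ctp(s: DynamicSeries, aif: TimeDensityCurve) -> DynamicSeries:
    """Down-sample a CTP study to the 4 frames matching mCTA-P timing.

    Keeps the pre-contrast baseline (surrogate NCCT), the frame at peak
    arterial enhancement (time t_p), and the frames nearest t_p + 8 s and
    t_p + 16 s (ties resolved to the earlier frame).  Frame values and
    timestamps are taken unmodified from the source series.
    """
    if len(aif.times) != s.n_frames or not np.allclose(aif.times, s.times):
        raise ValueError("the AIF must be sampled on the source frame grid")
    i_peak = int(np.argmax(aif.values))
    if i_peak == 0:
        raise ValueError(
            "AIF peaks at the first frame: no baseline separation"
        )
    t_peak = float(s.times[i_peak])
    if t_peak + 16.0 > s.times[-1] + 1e-9:
        raise ValueError("t_peak + 16 s is beyond the last acquired frame")
    idxs = [0, i_peak]
    for target in (t_peak + 8.0, t_peak + 16.0):
        idxs.append(int(np.argmin(np.abs(s.times - target))))
    if not all(a < b for a, b in zip(idxs, idxs[1:])):
        raise ValueError("selected frames are not strictly increasing in time")
    return s.with_frames(s.frames[..., idxs].copy(), s.times[idxs].copy())


def assemble_mcta_p(
    ncct: np.ndarray,
    phases,
    brain_mask: np.ndarray,
    spacing,
    bias_hu: float = 4.0,
    protocol: AcquisitionProtocol | None = None,
    hemisphere_labels: np.ndarray | None = None,
) -> DynamicSeries:
    """Assemble an mCTA-P series from pre-aligned NCCT + 3 mCTA phases.

    ``bias_hu`` is subtracted from brain voxels of the three phase frames
    only (zeroth-order scatter-bias correction); the NCCT frame and non-brain
    voxels are untouched.
    """
    if protocol is None:
        protocol = AcquisitionProtocol.mcta_p(bias_hu=bias_hu)
    phases = list(phases)
    if len(phases) != 3:
        raise ValueError("exactly three mCTA phases are required")
    for p in phases:
        if p.shape != ncct.shape:
            raise ValueError("NCCT and mCTA phases must share one grid")
    if brain_mask.shape != ncct.shape:
        raise ValueError("brain mask shape must match the image grid")
    frames = np.stack([ncct] + phases, axis=-1).astype(float)
    for j in range(1, 4):
        frame = frames[..., j]
        frame[brain_mask] -= bias_hu
    return DynamicSeries(
        frames=frames,
        times=np.asarray(protocol.frame_times),
        spacing=spacing,
        brain_mask=brain_mask,
        hemisphere_labels=hemisphere_labels,
    )


def correct_mcta_bias(s: DynamicSeries, bias_hu: float) -> DynamicSeries:
    """Subtract an additive HU bias from brain voxels of post-baseline frames."""
    if s.brain_mask is None:
        raise ValueError("bias correction requires a brain mask")
    frames = s.frames.copy()
    for j in range(1, s.n_frames):
        frame = frames[..., j]
        frame[s.brain_mask] -= bias_hu
    return s.with_frames(frames, s.times.copy())


def slab_average(
    s: DynamicSeries, slab_mm: float = 10.0, step_mm: float = 5.0
) -> DynamicSeries:
    """Average thin axial slices into overlapping thick slabs.

    Each output slice is the mean of the input slices whose axial position
    falls in a ``slab_mm`` window; windows are spaced ``step_mm`` apart.
    With the defaults, adjacent slabs share half their member slices.
    """
    dz = s.spacing[2]
    nz = s.frames.shape[2]
    extent = nz * dz
    if extent + 1e-9 < slab_mm:
        raise ValueError(
            f"axial extent {extent:.2f} mm is smaller than the slab "
            f"thickness {slab_mm} mm"
        )
    z = np.arange(nz) * dz
    n_out = int(np.floor((extent - slab_mm) / step_mm + 1e-9)) + 1
    members = [
        np.flatnonzero((z >= k * step_mm - 1e-9) & (z < k * step_mm + slab_mm - 1e-9))
        for k in range(n_out)
    ]
    frames = np.stack(
        [s.frames[:, :, m, :].mean(axis=2) for m in members], axis=2
    )
    new_spacing = (s.spacing[0], s.spacing[1], step_mm)

    def _reduce_mask(mask):
        if mask is None:
            return None
        return np.stack(
            [mask[:, :, m].mean(axis=2) >= 0.5 for m in members], axis=2
        )

    brain = _reduce_mask(s.brain_mask)
    hemi = None
    if s.hemisphere_labels is not None:
        # majority label within each slab
        hemi = np.stack(
            [
                np.apply_along_axis(
                    lambda v: np.bincount(v, minlength=3).argmax(),
                    2,
                    s.hemisphere_labels[:, :, m].astype(int),
                )
                for m in members
            ],
            axis=2,
        )
    return DynamicSeries(
        frames=frames,
        times=s.times.copy(),
        spacing=new_spacing,
        brain_mask=brain,
        hemisphere_labels=hemi,
    )
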