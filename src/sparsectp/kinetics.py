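"""Johnson-Wilson-Lee (JWL) impulse-residue kinetics.

The JWL model describes the fate of an intravascular contrast bolus in a
capillary bed with an impulse residue function R(t):

* ``0`` before the arterial-to-tissue arrival delay ``T0``,
* ``1`` on the plateau ``[T0, T0 + W)`` where ``W`` is the minimum capillary
  transit time,
* ``E * exp(-k (t - T0 - W))`` afterwards, the fraction ``E`` of tracer with
  transit time longer than ``W`` clearing at rate ``k``.

Throughout this package ``k`` is fixed to 0 (slow late clearance is modelled
as a constant tail), so the residue is a delayed box of height 1 with a
constant tail of height ``E``.  A tissue time-density curve (TDC) is the
convolution of the arterial input function Ca(t) with ``F * R(t)``, where
``F`` is tissue perfusion (flow).  Summary haemodynamic parameters follow
from the residue function: CBV is the area under ``F * R``, MTT = CBV / CBF
(Central Volume Principle), and Tmax = T0 + MTT / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeDensityCurve",
    "KineticParams",
    "SummaryParams",
    "GammaVariate",
    "impulse_residue",
    "tissue_forward",
    "derive_summary",
]


@dataclass
class TimeDensityCurve:
    """A sampled time-density curve: HU enhancement versus time (seconds)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) < 2:
            raise ValueError("a time-density curve needs at least 2 samples")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def peak_value(self) -> float:
        return float(self.values.max())

    @property
    def peak_time(self) -> float:
        return float(self.times[int(np.argmax(self.values))])

    def auc(self) -> float:
        """Trapezoidal area under the curve."""
        return float(np.trapezoid(self.values, self.times))

    def is_uniform(self, atol: float = 1e-9) -> bool:
        steps = np.diff(self.times)
        return bool(np.allclose(steps, steps[0], atol=atol))


@dataclass(frozen=True)
class GammaVariate:
    """Gamma-variate bolus curve, parameterised by its peak.

    ``value(t) = peak_hu * (x / (alpha * scale_s))**alpha * exp(alpha - x / scale_s)``
    for ``x = t - onset_s > 0``, else 0.  The maximum (``peak_hu``) occurs
    at ``onset_s + alpha * scale_s``.  The standard first-pass bolus model
    for contrast enhancement curves.
    """

    peak_hu: float = 200.0
    onset_s: float = 7.0
    alpha: float = 3.0
    scale_s: float = 3.0

    @property
    def peak_time(self) -> float:
        return self.onset_s + self.alpha * self.scale_s

    def value(self, t) -> np.ndarray:
        t = np.asarray(t, float)
        x = t - self.onset_s
        with np.errstate(invalid="ignore"):
            v = np.where(
                x > 0,
                (x / (self.alpha * self.scale_s)) ** self.alpha
                * np.exp(self.alpha - x / self.scale_s),
                0.0,
            )
        return self.peak_hu * np.nan_to_num(v)


@dataclass(frozen=True)
class KineticParams:
    """JWL parameters for one voxel.

    t0
        Arrival delay from artery to tissue, seconds, >= 0.
    w
        Minimum capillary transit time, seconds, > 0.
    f
        Flow amplitude in HU-tissue per HU-artery per second, >= 0.  Relative
        (percent-of-contralateral) thresholds make the absolute calibration
        irrelevant; an optional display scale converts to ml/min/100g.
    e
        Fraction of tracer with transit time > w, in [0, 1].
    k
        Late clearance rate, fixed to 0 in this implementation.
    """

    t0: float
    w: float
    f: float
    e: float = 0.0
    k: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.t0, self.w, self.f, self.e, self.k]).all():
            raise ValueError("kinetic parameters must be finite")
        if self.t0 < 0:
            raise ValueError(f"t0 must be >= 0, got {self.t0}")
        if self.w <= 0:
            raise ValueError(f"w must be > 0, got {self.w}")
        if self.f < 0:
            raise ValueError(f"f must be >= 0, got {self.f}")
        if not 0.0 <= self.e <= 1.0:
            raise ValueError(f"e must be in [0, 1], got {self.e}")
        if self.k != 0.0:
            raise ValueError("k is fixed to 0 in this implementation")


@dataclass(frozen=True)
class SummaryParams:
    """Derived summary perfusion parameters for one voxel."""

    cbf: float
    cbv: float
    mtt: float
    tmax: float


def impulse_residue(t, p: KineticParams):
    """Evaluate the JWL impulse residue function R(t) (k = 0).

    Returns 0 for ``t < t0``, 1 on ``[t0, t0 + w)`` and ``e`` for
    ``t >= t0 + w``.  Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    if not np.isfinite(t).all():
        raise ValueError("t must be finite")
    out = np.where(t < p.t0, 0.0, np.where(t < p.t0 + p.w, 1.0, p.e))
    if out.ndim == 0:
        return float(out)
    return out


def tissue_forward(
    aif: TimeDensityCurve, p: KineticParams, sample_times
) -> TimeDensityCurve:
    """Forward tissue curve Q(t) = F * (Ca conv R)(t).

    The convolution is discrete on the AIF grid with left-edge sample-and-hold
    of R, i.e. ``Q(t) = F * sum_j Ca(t_j) R(t - t_j) dt``.  The AIF must be on
    a uniform grid (resample first, e.g. with
    :func:`sparsectp.series.interpolate_to_1s`).
    """
    if not aif.is_uniform():
        raise ValueError(
            "AIF must be sampled on a uniform time grid; resample it first"
        )
    dt = float(aif.times[1] - aif.times[0])
    t = np.asarray(sample_times, dtype=float)
    lags = t[:, None] - aif.times[None, :]
    r = np.where(lags < p.t0, 0.0, np.where(lags < p.t0 + p.w, 1.0, p.e))
    q = p.f * (r * aif.values[None, :]).sum(axis=1) * dt
    return TimeDensityCurve(times=t, values=q)


def derive_summary(
    p: KineticParams, t_end: float, cbf_scale: float = 1.0
) -> SummaryParams:
    """Summary parameters from JWL parameters.

    CBV is the area under ``F * R(t)`` on ``[0, t_end]``; with k = 0 this is
    ``F * (W + E * (t_end - T0 - W))``.  MTT = CBV / CBF by the Central Volume
    Principle; Tmax = T0 + MTT / 2.  The convention for F == 0 is CBV = 0,
    MTT = 0, Tmax = T0.

    ``cbf_scale`` rescales CBF (and CBV) for display; the documented constant
    6000 / 1.04 yields ml/min/100g assuming brain density 1.04 g/ml.
    """
    if t_end <= p.t0 + p.w:
        raise ValueError(
            f"integration window too short: t_end={t_end} must exceed "
            f"t0 + w = {p.t0 + p.w}"
        )
    if p.f == 0.0:
        return SummaryParams(cbf=0.0, cbv=0.0, mtt=0.0, tmax=p.t0)
    cbv = p.f * (p.w + p.e * (t_end - p.t0 - p.w))
    mtt = cbv / p.f
    tmax = p.t0 + 0.5 * mtt
    return SummaryParams(
        cbf=p.f * cbf_scale, cbv=cbv * cbf_scale, mtt=mtt, tmax=tmax
    )
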