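"""Inter-method agreement statistics and threshold calibration.

Diagnostic agreement of the mismatch profile between a reference technique
(CTP) and a surrogate (dCTP or mCTA-P) is summarised by Cohen's kappa with a
95% CI, plus sensitivity / specificity / accuracy with the reference as
ground truth.  Lesion-volume agreement uses the Pearson correlation and
Bland-Altman limits of agreement (differences taken as reference minus
comparison).  A generic calibrator sweeps (relative-CBF, Tmax) threshold
grids to best match reference lesion volumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lesion import (
    LesionThresholds,
    hypoperfusion_mask,
    mask_volume_ml,
    postprocess_mask,
    segment_core,
    segment_penumbra,
)

__all__ = [
    "ConfusionTable2x2",
    "KappaResult",
    "BlandAltmanResult",
    "AgreementReport",
    "CalibrationCase",
    "cohens_kappa",
    "class_metrics",
    "pearson_r",
    "bland_altman",
    "agreement_report",
    "calibrate_thresholds",
]


@dataclass(frozen=True)
class ConfusionTable2x2:
    """2x2 confusion counts; favourable mismatch is the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            raise ValueError("the confusion table must contain observations")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    se: float


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    loa_low: float
    loa_high: float
    sd: float


@dataclass
class AgreementReport:
    """Aggregate agreement report for one comparison method."""

    kappa: KappaResult
    sensitivity_pct: float
    specificity_pct: float
    accuracy_pct: float
    core_pearson_r: float
    core_bland_altman: BlandAltmanResult
    penumbra_pearson_r: float
    penumbra_bland_altman: BlandAltmanResult


def _kappa_se_delta(p: np.ndarray, n: int, po: float, pe: float) -> float:
    """Large-sample SE of kappa (Fleiss, Cohen & Everitt delta method)."""
    rows = p.sum(axis=1)
    cols = p.sum(axis=0)
    term1 = 0.0
    for i in range(2):
        term1 += p[i, i] * ((1 - pe) - (rows[i] + cols[i]) * (1 - po)) ** 2
    term2 = 0.0
    for i in range(2):
        for j in range(2):
            if i != j:
                term2 += p[i, j] * (cols[i] + rows[j]) ** 2
    term2 *= (1 - po) ** 2
    term3 = (po * pe - 2 * pe + po) ** 2
    var = (term1 + term2 - term3) / (n * (1 - pe) ** 4)
    return float(np.sqrt(max(var, 0.0)))


def cohens_kappa(t: ConfusionTable2x2, se_method: str = "delta") -> KappaResult:
    """Cohen's kappa with a 95% confidence interval.

    ``se_method='delta'`` uses the exact large-sample (delta-method)
    variance; ``'simple'`` uses sqrt(po (1 - po) / (n (1 - pe)^2)).  When
    chance agreement pe equals 1 the kappa is defined as 1 for perfect
    observed agreement and 0 otherwise.
    """
    n = t.n
    p = np.array([[t.tp, t.fn], [t.fp, t.tn]], dtype=float) / n
    po = (t.tp + t.tn) / n
    pe = float(p.sum(axis=1) @ p.sum(axis=0))
    if pe >= 1.0 - 1e-15:
        kappa = 1.0 if po >= 1.0 - 1e-15 else 0.0
        return KappaResult(kappa=kappa, ci_low=kappa, ci_high=kappa, se=0.0)
    kappa = (po - pe) / (1.0 - pe)
    if se_method == "delta":
        se = _kappa_se_delta(p, n, po, pe)
    elif se_method == "simple":
        se = float(np.sqrt(po * (1 - po) / (n * (1 - pe) ** 2)))
    else:
        raise ValueError(f"unknown se_method: {se_method!r}")
    half = 1.96 * se
    return KappaResult(
        kappa=float(kappa),
        ci_low=float(max(kappa - half, -1.0)),
        ci_high=float(min(kappa + half, 1.0)),
        se=se,
    )


def class_metrics(t: ConfusionTable2x2):
    """(sensitivity %, specificity %, accuracy %); NaN if undefined."""
    sens = 100.0 * t.tp / (t.tp + t.fn) if (t.tp + t.fn) else np.nan
    spec = 100.0 * t.tn / (t.tn + t.fp) if (t.tn + t.fp) else np.nan
    acc = 100.0 * (t.tp + t.tn) / t.n
    return float(sens), float(spec), float(acc)


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation; NaN for constant input."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("paired samples of equal length >= 2 are required")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def bland_altman(reference, comparison) -> BlandAltmanResult:
    """Bland-Altman mean difference and 95% limits of agreement.

    Differences are ``reference - comparison``; the limits are
    MD +/- 1.96 * SD with the sample (n-1) standard deviation.
    """
    reference = np.asarray(reference, float)
    comparison = np.asarray(comparison, float)
    if reference.shape != comparison.shape or reference.size < 2:
        raise ValueError("paired samples of equal length >= 2 are required")
    d = reference - comparison
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=md, loa_low=md - 1.96 * sd, loa_high=md + 1.96 * sd, sd=sd
    )


def agreement_report(
    ref_profiles,
    cmp_profiles,
    ref_core,
    cmp_core,
    ref_penumbra,
    cmp_penumbra,
    positive: str = "favourable",
) -> AgreementReport:
    """Build the full agreement report from per-case labels and volumes."""
    ref = np.asarray(ref_profiles) == positive
    cmp_ = np.asarray(cmp_profiles) == positive
    table = ConfusionTable2x2(
        tp=int(np.sum(ref & cmp_)),
        fn=int(np.sum(ref & ~cmp_)),
        fp=int(np.sum(~ref & cmp_)),
        tn=int(np.sum(~ref & ~cmp_)),
    )
    sens, spec, acc = class_metrics(table)
    return AgreementReport(
        kappa=cohens_kappa(table),
        sensitivity_pct=sens,
        specificity_pct=spec,
        accuracy_pct=acc,
        core_pearson_r=pearson_r(ref_core, cmp_core),
        core_bland_altman=bland_altman(ref_core, cmp_core),
        penumbra_pearson_r=pearson_r(ref_penumbra, cmp_penumbra),
        penumbra_bland_altman=bland_altman(ref_penumbra, cmp_penumbra),
    )


@dataclass
class CalibrationCase:
    """One case of the threshold-calibration cohort.

    Candidate maps (relative CBF in %, Tmax in s) with validity and
    laterality masks, plus the reference core / penumbra volumes in ml.
    """

    rcbf_map: np.ndarray
    tmax_map: np.ndarray
    valid_mask: np.ndarray
    ipsi_mask: np.ndarray
    spacing: tuple
    ref_core_ml: float
    ref_penumbra_ml: float


class _MapsView:
    """Minimal maps adapter for the lesion segmentation functions."""

    def __init__(self, case: CalibrationCase):
        self.tmax = case.tmax_map
        self.valid_mask = case.valid_mask


def calibrate_thresholds(
    cases,
    rcbf_grid,
    tmax_grid,
    tmax_hypoperfusion_s: float = 4.0,
    min_component_ml: float = 1.0,
    postprocess: bool = False,
):
    """Sweep (rCBF %, Tmax s) grids to best match reference lesion volumes.

    The objective for a grid pair is the mean over cases of
    |core - ref_core| + |penumbra - ref_penumbra|.  Returns
    ``(best_rcbf, best_tmax, objective_table)`` with the full objective as a
    DataFrame (rows: rCBF, columns: Tmax); ties resolve to the smaller
    thresholds.
    """
    cases = list(cases)
    if len(cases) < 2:
        raise ValueError("at least 2 calibration cases are required")
    rcbf_grid = sorted(float(v) for v in rcbf_grid)
    tmax_grid = sorted(float(v) for v in tmax_grid)
    if not rcbf_grid or not tmax_grid:
        raise ValueError("threshold grids must be non-empty")

    table = pd.DataFrame(index=rcbf_grid, columns=tmax_grid, dtype=float)
    best = (np.inf, None, None)
    for rcbf in rcbf_grid:
        for tmax in tmax_grid:
            th = LesionThresholds(
                rcbf_core_pct=rcbf,
                tmax_penumbra_s=tmax,
                tmax_hypoperfusion_s=tmax_hypoperfusion_s,
                min_component_ml=min_component_ml,
            )
            errs = []
            for case in cases:
                maps = _MapsView(case)
                hypo = hypoperfusion_mask(maps, case.ipsi_mask, th)
                core = segment_core(case.rcbf_map, th, hypo)
                pen = segment_penumbra(maps, th, hypo, core)
                if postprocess:
                    core = postprocess_mask(core, case.spacing, min_component_ml)
                    pen = postprocess_mask(pen, case.spacing, min_component_ml)
                    pen &= ~core
                core_ml = mask_volume_ml(core, case.spacing)
                pen_ml = mask_volume_ml(pen, case.spacing)
                errs.append(
                    abs(core_ml - case.ref_core_ml)
                    + abs(pen_ml - case.ref_penumbra_ml)
                )
            obj = float(np.mean(errs))
            table.loc[rcbf, tmax] = obj
            if obj < best[0]:
                best = (obj, rcbf, tmax)
    return best[1], best[2], table
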