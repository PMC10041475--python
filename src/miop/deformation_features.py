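"""Waveform features of modal profiles and the mIOP estimator.

The modal profile of each mode is a per-frame time series; its areas under
the curve over fixed windows act as energy-like summaries (the air-puff
loading profile is the same for every exam, so the AUC is proportional to
the work done on that modal shape).  Ratios of these AUCs cancel the
amplitude scale set by corneal thickness and stiffness, which is the
"self-calibration" property that makes the M4 ratio a usable pressure index:

    mIOP = 0.586 * (M4 AUC over frames 1-140) / (M4 AUC over frames 24-40)
           + 8.2698   [mmHg]

Windows
-------
* rising phase: frames 24-40 (puff onset to around first applanation); the
  fixed frame range is the operational definition used throughout.
* downward phase: second applanation (A2) to frame 140.

AUCs are signed (coefficients may be negative) and integrate over the frame
index, so the frame interval cancels in every ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict

import numpy as np
import pandas as pd

from .contour_core import DeformationSequence, _kasa_circle
from .errors import (
    DegenerateFeature,
    DegenerateGeometry,
    DomainError,
    NoApplanation,
    RangeError,
)
from .modal_decomposition import ModalProfileMatrix

RISING_WINDOW = (24, 40)  # frames, inclusive
MIOP_SLOPE = 0.586  # mmHg per AUC-ratio unit
MIOP_INTERCEPT = 8.2698  # mmHg
CALIBRATED_IOP_RANGE = (8.0, 30.0)  # mmHg

__all__ = [
    "ApplanationFrames",
    "SecondaryRatios",
    "MiopModel",
    "auc",
    "detect_applanation_frames",
    "secondary_ratios",
    "miop",
    "performance_score",
    "primary_features",
    "RISING_WINDOW",
]


@dataclass(frozen=True)
class ApplanationFrames:
    """First (inward) and second (rebound) applanation frame indices."""

    A1: int
    A2: int

    def __post_init__(self) -> None:
        if not (1 < self.A1 < self.A2 <= 140):
            raise NoApplanation(
                f"applanation frames out of order: A1={self.A1}, A2={self.A2}"
            )


@dataclass(frozen=True)
class MiopModel:
    """Published linear calibration from the M4 AUC ratio to mmHg."""

    slope: float = MIOP_SLOPE
    intercept: float = MIOP_INTERCEPT

    def __call__(self, ratio: float) -> float:
        return self.slope * ratio + self.intercept


@dataclass(frozen=True)
class SecondaryRatios:
    """The ten AUC-ratio parameters (modes 1..5, rising and downward).

    ``rising[n] = AUC(1,140) / AUC(24,40)`` and
    ``down[n] = AUC(1,140) / AUC(A2,140)`` of mode n's profile.
    """

    rising: Dict[int, float]
    down: Dict[int, float]

    @property
    def m4_rising(self) -> float:
        """The M4 ratio — the single input of the mIOP model."""
        return self.rising[4]


def auc(series: np.ndarray, i: int, j: int) -> float:
    """Signed trapezoid AUC of a per-frame series over frames i..j inclusive.

    Integration is over the frame index, so the window i..j has width j - i.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if not (1 <= i < j <= n):
        raise RangeError(f"invalid frame range [{i}, {j}] for {n} frames")
    return float(np.trapezoid(series[i - 1 : j], dx=1.0))


def _central_curvature(x: np.ndarray, z: np.ndarray, aperture_mm: float) -> float:
    """Signed curvature (1/mm) of the central contour from a circle fit.

    Positive while the surface is convex toward the camera (center of the
    fitted circle on the eye side); negative once the surface inverts.
    Near-flat configurations return ~0.
    """
    mask = np.abs(x) <= aperture_mm
    xs, zs = x[mask], z[mask]
    if len(xs) < 3:
        raise RangeError("fewer than 3 contour points inside the aperture")
    try:
        cx, cz, r = _kasa_circle(xs, zs)
    except DegenerateGeometry:
        return 0.0
    sign = 1.0 if cz > float(np.mean(zs)) else -1.0
    return sign / r


def detect_applanation_frames(
    seq: DeformationSequence,
    aperture_mm: float = 1.0,
    kappa_tol: float = 0.005,
) -> ApplanationFrames:
    """Locate the two applanation moments from central curvature.

    Per frame, a circle is fitted to the central ``|x| <= aperture_mm`` and
    the signed curvature tracked; A1 is the first frame at which it drops to
    ``<= kappa_tol`` (flat within tolerance) and A2 the last such frame of
    the concave episode.
    """
    kappa = np.array(
        [_central_curvature(f.x, f.z, aperture_mm) for f in seq.frames]
    )
    flat = np.flatnonzero(kappa <= kappa_tol)
    if flat.size == 0:
        raise NoApplanation("central curvature never crosses the flat threshold")
    return ApplanationFrames(A1=int(flat[0]) + 1, A2=int(flat[-1]) + 1)


def secondary_ratios(
    mp: ModalProfileMatrix, app: ApplanationFrames
) -> SecondaryRatios:
    """Compute the ten AUC-ratio parameters from a modal profile matrix."""
    if app.A2 >= mp.n_frames:
        raise RangeError("second applanation must precede the final frame")
    rising, down = {}, {}
    for n in range(1, min(mp.max_order, 5) + 1):
        row = mp.mode(n)
        total = auc(row, 1, mp.n_frames)
        d_rise = auc(row, *RISING_WINDOW)
        d_down = auc(row, app.A2, mp.n_frames)
        if max(abs(total), abs(d_rise), abs(d_down)) < 1e-9:
            # Mode never excited (e.g. odd modes with a perfectly centered
            # puff) up to sub-picometre numerical dust: the 0/0 ratio is
            # undefined but not an error.
            rising[n] = down[n] = float("nan")
            continue
        if abs(d_rise) < 1e-12 or abs(d_down) < 1e-12:
            raise DegenerateFeature(
                f"mode {n}: phase AUC is numerically zero; ratio undefined"
            )
        rising[n] = total / d_rise
        down[n] = total / d_down
    return SecondaryRatios(rising=rising, down=down)


def miop(ratio_rising_4: float, model: MiopModel = MiopModel()) -> float:
    """Estimate IOP (mmHg) from the M4 rising-phase AUC ratio.

    Warns (does not fail) when the estimate leaves the 8-30 mmHg range the
    calibration was established on.
    """
    if not np.isfinite(ratio_rising_4):
        raise DomainError("M4 ratio must be finite")
    value = model(float(ratio_rising_4))
    lo, hi = CALIBRATED_IOP_RANGE
    if not lo <= value <= hi:
        warnings.warn(
            f"mIOP {value:.2f} mmHg outside calibrated range {lo}-{hi} mmHg",
            stacklevel=2,
        )
    return value


def performance_score(
    r_iop_corvis: float,
    r_iop_pach: float,
    r_age: float,
    r_radius: float,
    r_cct: float,
) -> float:
    """Candidate-screening score from signed Pearson correlations.

    Rewards correlation with the two reference IOP readings and penalizes
    correlation with the confounders age, corneal radius and CCT:

        score = (r_IOP-Corvis + r_IOP-Pach)/2 - (r_age + r_radius + r_cct)/3

    An ideal pressure index scores 1; the score is bounded in [-2, 2].
    """
    rs = (r_iop_corvis, r_iop_pach, r_age, r_radius, r_cct)
    for r in rs:
        if not np.isfinite(r) or abs(r) > 1 + 1e-12:
            raise DomainError("correlation coefficients must lie in [-1, 1]")
    return (r_iop_corvis + r_iop_pach) / 2.0 - (r_age + r_radius + r_cct) / 3.0


def primary_features(
    mp: ModalProfileMatrix, app: ApplanationFrames
) -> pd.DataFrame:
    """Representative per-mode waveform features.

    One row per mode 0..N with the initial/final coefficient values, the
    signed extremum (largest magnitude, earliest frame on ties) and its
    frame, the least-squares slope over the rising window, and the
    total/rising/downward AUCs.  This is a documented representative catalog
    of classical waveform descriptors, not an exhaustive one.
    """
    rows = []
    r0, r1 = RISING_WINDOW
    frames_rise = np.arange(r0, r1 + 1, dtype=float)
    for n in range(mp.max_order + 1):
        row = mp.mode(n)
        ext_idx = int(np.argmax(np.abs(row)))  # first occurrence on ties
        slope = np.polyfit(frames_rise, row[r0 - 1 : r1], 1)[0]
        rows.append(
            {
                "mode": n,
                "initial": row[0],
                "final": row[-1],
                "extremum": row[ext_idx],
                "extremum_frame": ext_idx + 1,
                "rising_slope": slope,
                "auc_total": auc(row, 1, mp.n_frames),
                "auc_rising": auc(row, r0, r1),
                "auc_down": auc(row, app.A2, mp.n_frames),
            }
        )
    return pd.DataFrame(rows).set_index("mode")
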