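"""Domain types and geometry for anterior corneal contour sequences.

An air-puff tonometer records ~140 cross-sectional frames of the cornea over
roughly 32 ms.  This module holds the per-frame contour containers, CSV I/O,
smoothing-spline fitting, the reference-circle fit that supplies the corneal
curvature radius, and the mapping from Cartesian contours to angular
deflection profiles ``u(theta)`` on which the modal decomposition operates.

Conventions
-----------
* ``x`` is the signed lateral position in mm from the corneal apex; the apex
  is the minimum-``z`` point of the smoothed first frame (ties broken toward
  ``x = 0``).
* ``z`` is in mm and increases away from the camera, toward the eye; the
  undeformed cornea is therefore convex toward small ``z``.
* Frame indices are 1-based and ranges are inclusive ("frames 1-140").
* The deflection ``u`` defaults to the vertical difference against the first
  (undeformed) frame, so the zeroth mode cleanly captures whole-eye movement;
  a raw radial variant (distance to the reference circle) is kept as an
  option.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import least_squares

from .errors import (
    DegenerateGeometry,
    FormatError,
    GeometryError,
    InsufficientData,
    SequenceError,
)

DEFAULT_DT_MS = 32.0 / 140.0
DEFAULT_THETA_R = 0.6  # rad, half-aperture of the angular integration region
DEFAULT_GRID_POINTS = 241

__all__ = [
    "ContourFrame",
    "DeformationSequence",
    "CircleFit",
    "AngularProfile",
    "SequenceMeta",
    "read_sequence_csv",
    "write_sequence_csv",
    "smooth_contour",
    "fit_reference_circle",
    "to_angular_profile",
]


@dataclass(frozen=True)
class ContourFrame:
    """One frame's anterior contour as ``(x, z)`` samples in mm."""

    frame_index: int
    time_ms: float
    x: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        z = np.asarray(self.z, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "z", z)
        if x.ndim != 1 or z.ndim != 1 or len(x) != len(z):
            raise FormatError("x and z must be 1-D arrays of equal length")
        if len(x) < 2:
            raise InsufficientData("a contour needs at least 2 points")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(z))):
            raise FormatError("contour contains non-finite values")
        if np.any(np.diff(x) <= 0):
            raise FormatError("x must be strictly increasing")

    @property
    def n_points(self) -> int:
        return len(self.x)


@dataclass
class SequenceMeta:
    """Optional per-eye metadata and clinical covariates."""

    id: str = ""
    eye: str = ""
    dt_ms: float = DEFAULT_DT_MS
    iop_corvis: Optional[float] = None
    iop_pach: Optional[float] = None
    biop: Optional[float] = None
    age: Optional[float] = None
    cct_um: Optional[float] = None
    radius_mm: Optional[float] = None
    a1t_ms: Optional[float] = None
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "SequenceMeta":
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in d.items() if k in known}
        extra = {k: v for k, v in d.items() if k not in known}
        return cls(**kwargs, extra=extra)

    def to_dict(self) -> dict:
        out = {
            k: getattr(self, k)
            for k in self.__dataclass_fields__
            if k != "extra" and getattr(self, k) not in (None, "")
        }
        out.update(self.extra)
        return out


@dataclass
class DeformationSequence:
    """An ordered 140-frame deformation recording with metadata.

    ``partial`` is set (with a warning at read time) when fewer than the
    expected 140 frames are present; downstream quality control fails such
    sequences rather than silently analyzing them.
    """

    frames: list
    dt_ms: float = DEFAULT_DT_MS
    meta: SequenceMeta = field(default_factory=SequenceMeta)
    partial: bool = False
    expected_frames: int = 140

    def __post_init__(self) -> None:
        if not self.frames:
            raise SequenceError("sequence has no frames")
        idx = [f.frame_index for f in self.frames]
        if idx != sorted(idx):
            self.frames = sorted(self.frames, key=lambda f: f.frame_index)
            idx = [f.frame_index for f in self.frames]
        if idx[0] != 1 or idx != list(range(1, len(idx) + 1)):
            raise SequenceError("frame_index must be contiguous from 1")
        if len(self.frames) != self.expected_frames and not self.partial:
            raise SequenceError(
                f"expected {self.expected_frames} frames, got {len(self.frames)}; "
                "pass partial=True to accept"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def times_ms(self) -> np.ndarray:
        return (np.arange(self.n_frames)) * self.dt_ms


@dataclass(frozen=True)
class CircleFit:
    """Least-squares circle through contour points (mm)."""

    center_x: float
    center_z: float
    radius: float
    rms_residual: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise DegenerateGeometry("circle radius must be positive")


@dataclass(frozen=True)
class AngularProfile:
    """Deflection ``u`` versus normalized angular coordinate ``s``.

    ``s = theta / theta_R`` maps the half-aperture ``theta_R`` (~0.6 rad) onto
    [-1, 1], the natural domain of the Legendre basis.
    """

    s: np.ndarray
    theta: np.ndarray
    theta_R: float
    u: np.ndarray
    frame_index: int
    basis_convention: str = "normalized"

    def __post_init__(self) -> None:
        if np.any(np.abs(self.theta) > self.theta_R * (1 + 1e-9)):
            raise GeometryError("theta exceeds the half-aperture theta_R")
        if not np.all(np.isfinite(self.u)):
            raise GeometryError("deflection contains non-finite values")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("frame", "x_mm", "z_mm")


def _find_meta_sidecar(path: Path) -> Optional[Path]:
    for suffix in (".meta.json", ".meta.yaml", ".meta.yml"):
        candidate = path.with_suffix("").with_suffix("")  # strip .csv
        candidate = path.parent / (path.stem + suffix)
        if candidate.exists():
            return candidate
    return None


def read_sequence_csv(
    path,
    sep: str = ",",
    meta_path=None,
    expected_frames: int = 140,
) -> DeformationSequence:
    """Read a contour sequence from CSV (columns ``frame,x_mm,z_mm``).

    A metadata sidecar ``<stem>.meta.json`` / ``.meta.yaml`` next to the CSV
    is loaded automatically when present.  Fewer than ``expected_frames``
    frames produces a warning and a sequence flagged ``partial``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    meta = SequenceMeta()
    sidecar = Path(meta_path) if meta_path is not None else _find_meta_sidecar(path)
    if sidecar is not None and sidecar.exists():
        with open(sidecar) as fh:
            raw = json.load(fh) if sidecar.suffix == ".json" else yaml.safe_load(fh)
        meta = SequenceMeta.from_dict(raw or {})
    if not meta.id:
        meta.id = path.stem

    frame_ids = np.sort(df["frame"].unique()).astype(int)
    if frame_ids[0] != 1 or not np.array_equal(
        frame_ids, np.arange(1, len(frame_ids) + 1)
    ):
        raise SequenceError("frame numbers must be contiguous starting at 1")

    partial = len(frame_ids) < expected_frames
    if partial:
        warnings.warn(
            f"{path.name}: only {len(frame_ids)} of {expected_frames} frames; "
            "sequence flagged partial",
            stacklevel=2,
        )

    dt = float(meta.dt_ms) if meta.dt_ms else DEFAULT_DT_MS
    frames = []
    for fi, group in df.sort_values(["frame", "x_mm"]).groupby("frame", sort=True):
        frames.append(
            ContourFrame(
                frame_index=int(fi),
                time_ms=(int(fi) - 1) * dt,
                x=group["x_mm"].to_numpy(dtype=float),
                z=group["z_mm"].to_numpy(dtype=float),
            )
        )
    return DeformationSequence(
        frames=frames, dt_ms=dt, meta=meta, partial=partial,
        expected_frames=expected_frames if not partial else len(frames),
    )


def write_sequence_csv(seq: DeformationSequence, path, write_meta: bool = True) -> None:
    """Write a sequence to CSV in the ``frame,x_mm,z_mm`` dialect."""
    path = Path(path)
    parts = [
        pd.DataFrame({"frame": f.frame_index, "x_mm": f.x, "z_mm": f.z})
        for f in seq.frames
    ]
    pd.concat(parts, ignore_index=True).to_csv(path, index=False, float_format="%.9g")
    if write_meta:
        meta_path = path.parent / (path.stem + ".meta.json")
        with open(meta_path, "w") as fh:
            json.dump(seq.meta.to_dict(), fh, indent=1, default=float)


# ---------------------------------------------------------------------------
# Smoothing and circle geometry
# ---------------------------------------------------------------------------


def smooth_contour(frame: ContourFrame, smoothing: float = 0.0) -> ContourFrame:
    """Fit a cubic smoothing spline and re-evaluate on the same x grid.

    ``smoothing`` is the roughness-penalty weight ``lam`` of the classical
    smoothing spline: 0 interpolates exactly, and as it grows the fit tends
    to the least-squares line of the data.
    """
    if frame.n_points < 8:
        raise InsufficientData("smoothing requires at least 8 points")
    if smoothing < 0:
        raise ValueError("smoothing must be non-negative")
    spline = make_smoothing_spline(frame.x, frame.z, lam=float(smoothing))
    return ContourFrame(
        frame_index=frame.frame_index,
        time_ms=frame.time_ms,
        x=frame.x.copy(),
        z=spline(frame.x),
    )


def _kasa_circle(x: np.ndarray, z: np.ndarray):
    """Algebraic (Kasa) circle fit; returns (cx, cz, r) or raises."""
    A = np.column_stack([2.0 * x, 2.0 * z, np.ones_like(x)])
    b = x**2 + z**2
    # Collinearity check on the centered coordinates.
    pts = np.column_stack([x - x.mean(), z - z.mean()])
    sv = np.linalg.svd(pts, compute_uv=False)
    if sv[0] == 0 or sv[-1] / sv[0] < 1e-10:
        raise DegenerateGeometry("points are (near-)collinear; no circle fit")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cz, c = sol
    r2 = c + cx**2 + cz**2
    if r2 <= 0:
        raise DegenerateGeometry("degenerate algebraic circle fit")
    return cx, cz, float(np.sqrt(r2))


def fit_reference_circle(frame: ContourFrame, aperture_mm: float = 4.0) -> CircleFit:
    """Fit a circle to the contour within ``|x| <= aperture_mm``.

    An algebraic Kasa fit seeds a geometric (orthogonal-distance) refinement.
    """
    mask = np.abs(frame.x) <= aperture_mm
    x, z = frame.x[mask], frame.z[mask]
    if len(x) < 3:
        raise InsufficientData("need at least 3 points within the aperture")
    cx, cz, r = _kasa_circle(x, z)

    def residual(p):
        return np.hypot(x - p[0], z - p[1]) - p[2]

    fit = least_squares(residual, x0=[cx, cz, r], method="lm")
    cx, cz, r = fit.x
    rms = float(np.sqrt(np.mean(residual(fit.x) ** 2)))
    return CircleFit(center_x=float(cx), center_z=float(cz), radius=float(r), rms_residual=rms)


# ---------------------------------------------------------------------------
# Angular deflection profiles
# ---------------------------------------------------------------------------


def _apex_index(x: np.ndarray, z: np.ndarray) -> int:
    zmin = z.min()
    candidates = np.flatnonzero(z == zmin)
    return int(candidates[np.argmin(np.abs(x[candidates]))])


def to_angular_profile(
    frame: ContourFrame,
    reference_frame: ContourFrame,
    circle: CircleFit,
    deflection_mode: str = "from_reference",
    theta_R: Optional[float] = None,
    n_grid: int = DEFAULT_GRID_POINTS,
    geometry_frame: Optional[ContourFrame] = None,
) -> AngularProfile:
    """Map a Cartesian contour to a deflection profile over signed angle.

    ``theta`` is the signed angle, at the reference-circle center, between
    each sample's ray and the apex ray of the reference frame.  With
    ``from_reference`` (default) the deflection is ``u = z_t(x) - z_ref(x)``
    interpolated on a common uniform x grid; ``raw_radial`` uses the
    distance-to-center minus the radius of the frame's own samples.

    ``geometry_frame`` optionally supplies a denoised version of the
    reference used only for the apex location and angular mapping — on noisy
    contours the raw argmin apex jitters laterally, which would shift the
    angular origin of every frame.
    """
    if deflection_mode not in ("from_reference", "raw_radial"):
        raise ValueError(f"unknown deflection_mode {deflection_mode!r}")
    lo = max(frame.x.min(), reference_frame.x.min())
    hi = min(frame.x.max(), reference_frame.x.max())
    if not lo < hi:
        raise GeometryError("frame and reference share no x support")
    xg = np.linspace(lo, hi, n_grid)
    z_ref = np.interp(xg, reference_frame.x, reference_frame.z)
    z_t = np.interp(xg, frame.x, frame.z)

    # The apex (angular origin) comes from the denoised geometry frame when
    # given: the raw argmin jitters laterally under noise.  The angular map
    # itself keeps the raw reference — dphi/dz vanishes at the apex, so it
    # is insensitive to sample noise where it matters.
    geom = geometry_frame if geometry_frame is not None else reference_frame
    apex = _apex_index(xg, np.interp(xg, geom.x, geom.z))
    phi = np.arctan2(xg - circle.center_x, circle.center_z - z_ref)
    theta = phi - phi[apex]

    if theta_R is None:
        theta_R = min(DEFAULT_THETA_R, float(np.max(np.abs(theta))))
    keep = np.abs(theta) <= theta_R * (1 + 1e-12)
    if keep.sum() < 2:
        raise GeometryError("no samples within the angular aperture")
    theta = np.clip(theta[keep], -theta_R, theta_R)

    if deflection_mode == "from_reference":
        u = (z_t - z_ref)[keep]
    else:
        u = (
            np.hypot(xg - circle.center_x, z_t - circle.center_z) - circle.radius
        )[keep]

    return AngularProfile(
        s=theta / theta_R,
        theta=theta,
        theta_R=float(theta_R),
        u=u,
        frame_index=frame.frame_index,
    )
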