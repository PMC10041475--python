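"""Legendre modal decomposition of angular deflection profiles.

The deforming anterior contour is represented as a truncated Legendre series

    u(s, t_i) = sum_{n=0..N} P_n(s) a_n(t_i),        s = theta / theta_R,

with the time series ``a_n(t_i)`` across the 140 frames forming the *modal
profiles*.  Even modes describe symmetric bending of the cornea (M0 is the
whole-eye-movement "breathing" mode), odd modes capture lateral misalignment
and rotation.  The pipeline truncates at N = 5.

Projection
----------
In the default ``normalized`` convention the coefficients are

    a_n = (2n+1)/2 * integral_{-1}^{1} u(s) P_n(s) ds,

evaluated by composite trapezoid quadrature on the sample grid.  Because
trapezoid sums are not exactly orthogonal on a finite grid, the raw
projections are corrected by the inverse of the discrete Gram matrix of the
basis (computed with the same quadrature weights on the same grid).  This
makes projection and synthesis exact mutual inverses for any profile in the
span of the basis, at any grid resolution, and converges to the plain
quadrature projection as the grid refines.

A ``literal_eq2`` convention, a_n = (2n+1)/2 * integral u(theta)
P_n(cos theta) sin(theta) d theta over [-theta_R, theta_R], is retained for
comparison.  Over a symmetric theta range its odd-weight integrand suppresses
the antisymmetric modes, which is why it is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .contour_core import (
    AngularProfile,
    CircleFit,
    ContourFrame,
    DeformationSequence,
    fit_reference_circle,
    to_angular_profile,
    DEFAULT_THETA_R,
)
from .errors import DomainError, InsufficientData

DEFAULT_MAX_ORDER = 5

__all__ = [
    "ModalCoefficients",
    "ModalProfileMatrix",
    "legendre_P",
    "legendre_design",
    "decompose_profile",
    "decompose_sequence",
    "reconstruct",
    "select_order_aic",
]


def legendre_P(n: int, x) -> np.ndarray:
    """Evaluate the Legendre polynomial P_n via the Bonnet recurrence.

    Accepts scalars or arrays with ``|x| <= 1 + 1e-12``.
    """
    if n < 0:
        raise DomainError("Legendre order must be non-negative")
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > 1 + 1e-12):
        raise DomainError("Legendre argument must lie in [-1, 1]")
    p_prev = np.ones_like(x)
    if n == 0:
        return p_prev if p_prev.ndim else float(p_prev)
    p = x.copy()
    for k in range(1, n):
        p, p_prev = ((2 * k + 1) * x * p - k * p_prev) / (k + 1), p
    return p if p.ndim else float(p)


def legendre_design(N: int, s: np.ndarray) -> np.ndarray:
    """Design matrix ``B[i, n] = P_n(s_i)`` for orders 0..N."""
    return np.column_stack([legendre_P(n, s) for n in range(N + 1)])


@dataclass(frozen=True)
class ModalCoefficients:
    """Modal displacements a_0..a_N (mm) of a single frame."""

    a: np.ndarray
    frame_index: int
    basis_convention: str = "normalized"

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        object.__setattr__(self, "a", a)
        if not np.all(np.isfinite(a)):
            raise DomainError("modal coefficients must be finite")

    @property
    def max_order(self) -> int:
        return len(self.a) - 1


@dataclass
class ModalProfileMatrix:
    """Matrix of modal profiles: rows are modes 0..N, columns are frames."""

    a: np.ndarray  # shape (N+1, n_frames), mm
    dt_ms: float
    basis_convention: str = "normalized"

    @property
    def max_order(self) -> int:
        return self.a.shape[0] - 1

    @property
    def n_frames(self) -> int:
        return self.a.shape[1]

    def mode(self, n: int) -> np.ndarray:
        return self.a[n]

    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_ms

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"frame": np.arange(1, self.n_frames + 1), "time_ms": self.times_ms()}
        for n in range(self.max_order + 1):
            cols[f"a{n}"] = self.a[n]
        return pd.DataFrame(cols)

    def write_csv(self, path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# basis_convention={self.basis_convention}\n")
            self.to_dataframe().to_csv(fh, index=False, float_format="%.9g")

    @classmethod
    def read_csv(cls, path, dt_ms: Optional[float] = None) -> "ModalProfileMatrix":
        path = Path(path)
        convention = "normalized"
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                if "basis_convention=" in first:
                    convention = first.split("basis_convention=")[1].strip()
                df = pd.read_csv(fh)
            else:
                fh.seek(0)
                df = pd.read_csv(fh)
        modes = [c for c in df.columns if c.startswith("a") and c[1:].isdigit()]
        modes.sort(key=lambda c: int(c[1:]))
        if dt_ms is None:
            t = df["time_ms"].to_numpy()
            dt_ms = float(t[1] - t[0]) if len(t) > 1 else 32.0 / 140.0
        return cls(
            a=df[modes].to_numpy().T.copy(), dt_ms=dt_ms, basis_convention=convention
        )


def _trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    w = np.zeros_like(grid)
    d = np.diff(grid)
    w[:-1] += d / 2
    w[1:] += d / 2
    return w


def decompose_profile(
    profile: AngularProfile,
    N: int = DEFAULT_MAX_ORDER,
    convention: str = "normalized",
    grid_corrected: bool = True,
) -> ModalCoefficients:
    """Project a deflection profile onto Legendre modes 0..N.

    ``grid_corrected`` (default) applies the discrete Gram-matrix correction
    described in the module docstring; set it to False for the plain
    quadrature projection.
    """
    m = len(profile.s)
    if m < 2 * (N + 1):
        raise InsufficientData(
            f"need at least {2 * (N + 1)} samples to resolve {N + 1} modes, got {m}"
        )
    factors = (2 * np.arange(N + 1) + 1) / 2.0
    if convention == "normalized":
        w = _trapezoid_weights(profile.s)
        B = legendre_design(N, profile.s)
        raw = factors * (B.T @ (w * profile.u))
        if grid_corrected:
            gram = factors[:, None] * (B.T @ (w[:, None] * B))
            a = np.linalg.solve(gram, raw)
        else:
            a = raw
    elif convention == "literal_eq2":
        w = _trapezoid_weights(profile.theta)
        B = legendre_design(N, np.cos(profile.theta))
        a = factors * (B.T @ (w * np.sin(profile.theta) * profile.u))
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return ModalCoefficients(
        a=a, frame_index=profile.frame_index, basis_convention=convention
    )


def reconstruct(coeffs: ModalCoefficients, s_grid: np.ndarray) -> np.ndarray:
    """Synthesize ``u(s) = sum_n a_n P_n(s)`` on the given grid."""
    B = legendre_design(coeffs.max_order, np.asarray(s_grid, dtype=float))
    return B @ coeffs.a


def _sequence_profiles(
    seq: DeformationSequence,
    deflection_mode: str,
    circle: Optional[CircleFit],
    theta_R: Optional[float],
):
    ref = seq.frames[0]
    # The apex location comes from a GCV-smoothed copy of the reference so
    # measurement noise cannot jitter the angular origin; deflections and the
    # angular map keep the raw reference samples.
    from scipy.interpolate import make_smoothing_spline

    spline = make_smoothing_spline(ref.x, ref.z)
    ref_geom = ContourFrame(
        frame_index=ref.frame_index, time_ms=ref.time_ms,
        x=ref.x.copy(), z=spline(ref.x),
    )
    if circle is None:
        circle = fit_reference_circle(ref)
    # theta_R is fixed from the first frame and reused for every frame so the
    # coefficients stay comparable across time.
    ref_profile = to_angular_profile(
        ref, ref, circle, deflection_mode, theta_R, geometry_frame=ref_geom
    )
    theta_R = ref_profile.theta_R
    profiles = [
        to_angular_profile(
            f, ref, circle, deflection_mode, theta_R, geometry_frame=ref_geom
        )
        for f in seq.frames
    ]
    return profiles, circle


def decompose_sequence(
    seq: DeformationSequence,
    N: int = DEFAULT_MAX_ORDER,
    convention: str = "normalized",
    deflection_mode: str = "from_reference",
    circle: Optional[CircleFit] = None,
    theta_R: Optional[float] = None,
) -> ModalProfileMatrix:
    """Decompose every frame of a sequence into modal coefficients.

    The reference circle is fitted on frame 1 unless supplied.
    """
    profiles, _ = _sequence_profiles(seq, deflection_mode, circle, theta_R)
    a = np.empty((N + 1, seq.n_frames))
    for j, prof in enumerate(profiles):
        a[:, j] = decompose_profile(prof, N=N, convention=convention).a
    return ModalProfileMatrix(a=a, dt_ms=seq.dt_ms, basis_convention=convention)


def select_order_aic(
    seq: DeformationSequence,
    N_max: int = 8,
    deflection_mode: str = "from_reference",
) -> int:
    """Pick the truncation order by the Akaike Information Criterion.

    For each candidate order the per-frame residual sum of squares of the
    reconstruction is converted to ``m * ln(RSS/m) + 2(N+1)`` and summed over
    frames; the argmin is returned, ties going to the smaller order.  This is
    a diagnostic; the pipeline itself uses the fixed order 5.
    """
    profiles, _ = _sequence_profiles(seq, deflection_mode, None, None)
    aic = np.zeros(N_max + 1)
    for N in range(N_max + 1):
        total = 0.0
        for prof in profiles:
            coeffs = decompose_profile(prof, N=N)
            resid = prof.u - reconstruct(coeffs, prof.s)
            m = len(prof.u)
            # Floor at a residual sd of 1e-11 mm so exact fits (which differ
            # only by solver round-off) tie instead of rewarding extra modes.
            rss = max(float(resid @ resid), m * 1e-22)
            total += m * np.log(rss / m) + 2 * (N + 1)
        aic[N] = total
    return int(np.argmin(aic))  # argmin takes the first (smallest N) on ties
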