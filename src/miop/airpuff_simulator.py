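"""Mode-space generative simulator of air-puff corneal deformation.

Raw tonometer recordings are not generally shareable, so the package ships a
synthetic generator that emits 140-frame contour sequences with controllable
pressure, thickness, whole-eye movement, lateral misalignment and contour
noise.  The generator works directly in mode space — it draws the modal
profiles a_n(t) from documented closed-form equations and synthesizes the
contours through the same Legendre basis the analysis uses — so every
recovery test has exact ground truth.  It deliberately emulates the
qualitative behavior expected of a pressurized cornea under an air puff
(single concave episode with two applanation crossings, pressure-dependent
modal timing and amplitude, whole-eye motion late in the sequence) without
claiming to be a mechanical model.

Generative equations (t in frames 1..140, defaults in SimConfig)
----------------------------------------------------------------
* envelope  env(t): smoothstep plateau turning on around frame 26 and off
  around frame 120 — the deformation episode.
* amplitude factor  amp = 1 / (1 + k_c (CCT-540)/540) * (16/IOP)^gamma_amp:
  thicker and more pressurized corneas deform less.
* a0(t) = wem_amp * smoothstep ramp after frame 90 (whole-eye movement).
* a2(t) = -c2 * amp * env(t): the main concave bending mode; its depth is
  what drives the central curvature through zero (applanation) and back.
* a4(t) = c4 * amp * [g1(t) + rho * g2(t)] with Gaussian lobes g1 centered
  near the first applanation (t_p1 = 32 - k1 (IOP-16), earlier at higher
  pressure) and g2 near the rebound (t_p2 = 95 + k2 (IOP-16), later at
  higher pressure), and rebound weight rho = rho0 * (IOP/16)^gamma_rebound.
  The first lobe sits inside the fixed rising window (frames 24-40), the
  second far outside it, so the total-to-rising AUC ratio of M4 grows
  strictly with IOP — the monotonicity the estimator relies on — while the
  amplitude factor cancels from the ratio entirely.
* odd modes a1, a3, a5 = misalign * odd_gain_n * env(t): linear in the
  misalignment angle, zero when the puff is centered.

All of this is deterministic given the configuration; only the additive
contour noise in :func:`synthesize_sequence` consumes random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .contour_core import (
    ContourFrame,
    DeformationSequence,
    SequenceMeta,
    write_sequence_csv,
)
from .errors import ConfigError
from .modal_decomposition import ModalProfileMatrix, legendre_design

__all__ = [
    "SimConfig",
    "SimTruth",
    "GrayscaleFrame",
    "simulate_modal_profiles",
    "synthesize_sequence",
    "simulate",
    "simulate_cohort",
    "render_frame_image",
    "write_cohort",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults describe a typical healthy eye."""

    iop: float = 16.0  # mmHg
    cct: float = 540.0  # um
    radius: float = 7.8  # mm, anterior curvature radius
    theta_R: float = 0.6  # rad, angular half-aperture
    wem_amp: float = 0.2  # mm, whole-eye movement amplitude
    misalign: float = 0.0  # rad, lateral puff misalignment
    noise_sd: float = 0.0  # mm, additive contour noise
    seed: int = 0
    n_frames: int = 140
    duration_ms: float = 32.0
    puff_onset_frame: int = 24
    n_points: int = 241
    age: float = 39.0  # years; recorded covariate, not a generator input

    # generator constants (documented package defaults)
    c2: float = 1.9  # mm, peak M2 bending amplitude at IOP 16 / CCT 540
    c4: float = 0.05  # mm, M4 lobe amplitude at IOP 16 / CCT 540
    k_c: float = 0.5  # CCT amplitude sensitivity
    gamma_amp: float = 0.3  # IOP amplitude exponent
    k1: float = 0.6  # frames/mmHg, first-lobe advance per mmHg
    k2: float = 0.8  # frames/mmHg, rebound-lobe delay per mmHg
    rho0: float = 1.0  # rebound-lobe weight at IOP 16
    gamma_rebound: float = 2.5  # IOP exponent of the rebound weight
    sigma1: float = 8.0  # frames, first-lobe width
    sigma2: float = 13.0  # frames, rebound-lobe width
    env_on: float = 26.0  # frames, envelope ramp-up start
    env_ramp_up: float = 12.0
    env_off: float = 120.0  # frames, envelope ramp-down end
    env_ramp_down: float = 14.0
    wem_onset: float = 90.0
    wem_ramp: float = 35.0
    odd_gain: tuple = (0.8, 0.5, 0.3)  # mm/rad for modes 1, 3, 5

    def __post_init__(self) -> None:
        if not 5.0 < self.iop < 40.0:
            raise ConfigError(f"iop {self.iop} outside the supported (5, 40) mmHg")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.n_frames != 140:
            raise ConfigError("sequences are fixed at 140 frames")
        if not 0 < self.theta_R < np.pi / 2:
            raise ConfigError("theta_R must lie in (0, pi/2)")
        if self.radius <= 0 or self.n_points < 16:
            raise ConfigError("radius must be positive and n_points >= 16")

    @property
    def dt_ms(self) -> float:
        return self.duration_ms / self.n_frames


@dataclass
class SimTruth:
    """A simulated eye: configuration, modal truth, emitted sequence."""

    config: SimConfig
    modal_truth: ModalProfileMatrix
    sequence: DeformationSequence
    a1_true: Optional[int]
    a2_true: Optional[int]


@dataclass
class GrayscaleFrame:
    """A rendered cross-sectional frame (top row is anterior / camera side)."""

    pixels: np.ndarray  # 2-D float intensities >= 0
    pixel_size: float  # mm per pixel, isotropic
    frame_index: int = 1
    truth_z_px: Optional[np.ndarray] = None  # per-column true edge row
    truth_x_mm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ConfigError("pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ConfigError("intensities must be finite and non-negative")
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size must be positive")


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def simulate_modal_profiles(config: SimConfig) -> ModalProfileMatrix:
    """Ground-truth modal profiles for one simulated eye (deterministic)."""
    t = np.arange(1, config.n_frames + 1, dtype=float)
    env = _smoothstep((t - config.env_on) / config.env_ramp_up) * _smoothstep(
        (config.env_off - t) / config.env_ramp_down
    )
    amp = (1.0 / (1.0 + config.k_c * (config.cct - 540.0) / 540.0)) * (
        16.0 / config.iop
    ) ** config.gamma_amp

    t_p1 = 32.0 - config.k1 * (config.iop - 16.0)
    t_p2 = 95.0 + config.k2 * (config.iop - 16.0)
    rho = config.rho0 * (config.iop / 16.0) ** config.gamma_rebound
    lobe1 = np.exp(-(((t - t_p1) / config.sigma1) ** 2))
    lobe2 = np.exp(-(((t - t_p2) / config.sigma2) ** 2))

    a = np.zeros((6, config.n_frames))
    a[0] = config.wem_amp * _smoothstep((t - config.wem_onset) / config.wem_ramp)
    a[2] = -config.c2 * amp * env
    a[4] = config.c4 * amp * (lobe1 + rho * lobe2)
    for mode, gain in zip((1, 3, 5), config.odd_gain):
        a[mode] = config.misalign * gain * env
    return ModalProfileMatrix(a=a, dt_ms=config.dt_ms, basis_convention="normalized")


def _apex_curvature(truth: ModalProfileMatrix, config: SimConfig) -> np.ndarray:
    """Analytic apex curvature (1/mm) of the synthesized surface per frame.

    kappa(t) = 1/R + sum_n a_n(t) P_n''(0) / (R * theta_R)^2 with
    P2''(0) = 3 and P4''(0) = -7.5 (odd modes and P0 do not bend the apex).
    """
    scale = (config.radius * config.theta_R) ** 2
    return 1.0 / config.radius + (3.0 * truth.a[2] - 7.5 * truth.a[4]) / scale


def _true_applanations(
    truth: ModalProfileMatrix, config: SimConfig, kappa_tol: float = 0.005
):
    kappa = _apex_curvature(truth, config)
    flat = np.flatnonzero(kappa <= kappa_tol)
    if flat.size == 0:
        return None, None
    return int(flat[0]) + 1, int(flat[-1]) + 1


def synthesize_sequence(
    truth: ModalProfileMatrix,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> DeformationSequence:
    """Render modal truth into a Cartesian contour sequence.

    Points sit on a uniform x grid spanning the configured aperture; the
    undeformed surface is the circle of the configured radius (apex at the
    origin, z toward the eye) and the per-frame deflection
    ``u(s, t) = sum_n a_n(t) P_n(s)`` is added vertically.  Gaussian noise of
    sd ``noise_sd`` is added to z when requested.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    R = config.radius
    x = np.linspace(-R * np.sin(config.theta_R), R * np.sin(config.theta_R),
                    config.n_points)
    s = np.arcsin(np.clip(x / R, -1, 1)) / config.theta_R
    z_ref = R - np.sqrt(R * R - x * x)
    B = legendre_design(truth.max_order, s)

    frames = []
    for j in range(truth.n_frames):
        z = z_ref + B @ truth.a[:, j]
        if config.noise_sd > 0:
            z = z + rng.normal(0.0, config.noise_sd, size=z.shape)
        frames.append(
            ContourFrame(frame_index=j + 1, time_ms=j * truth.dt_ms, x=x, z=z)
        )
    meta = SequenceMeta(
        dt_ms=truth.dt_ms,
        age=config.age,
        cct_um=config.cct,
        radius_mm=config.radius,
        extra={"iop_true": config.iop, "misalign": config.misalign,
               "seed": config.seed},
    )
    return DeformationSequence(frames=frames, dt_ms=truth.dt_ms, meta=meta)


def simulate(config: SimConfig) -> SimTruth:
    """Generate one eye: truth profiles, contour sequence, true applanations."""
    truth = simulate_modal_profiles(config)
    seq = synthesize_sequence(truth, config)
    a1, a2 = _true_applanations(truth, config)
    return SimTruth(config=config, modal_truth=truth, sequence=seq,
                    a1_true=a1, a2_true=a2)


def simulate_cohort(
    n: int,
    seed: int = 0,
    noise_sd: float = 0.002,
    base_config: Optional[SimConfig] = None,
) -> List[SimTruth]:
    """Sample a cohort of simulated eyes.

    Covariates are drawn to resemble a healthy adult screening population:
    IOP ~ Uniform(10, 22) mmHg, CCT ~ Normal(540, 38) um truncated to
    (450, 650), age ~ Normal(39, 14) years truncated to (18, 80) (recorded
    but not a generator input), misalignment ~ Normal(0, 0.02) rad.  Per-eye
    seeds derive from the master seed, so the same seed reproduces the same
    cohort exactly.
    """
    if n < 0:
        raise ConfigError("cohort size must be non-negative")
    base = base_config if base_config is not None else SimConfig()
    rng = np.random.default_rng(seed)

    def trunc_normal(mean, sd, lo, hi):
        while True:
            v = rng.normal(mean, sd)
            if lo < v < hi:
                return float(v)

    eyes = []
    for i in range(n):
        cfg = replace(
            base,
            iop=float(rng.uniform(10.0, 22.0)),
            cct=trunc_normal(540.0, 38.0, 450.0, 650.0),
            age=trunc_normal(39.0, 14.0, 18.0, 80.0),
            misalign=float(rng.normal(0.0, 0.02)),
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        truth = simulate(cfg)
        truth.sequence.meta.id = f"sim{i + 1:04d}"
        eyes.append(truth)
    return eyes


def write_cohort(eyes: List[SimTruth], out_dir) -> pd.DataFrame:
    """Write per-eye contour CSVs, a truth table and a covariate table.

    Returns the covariate table (also written as ``covariates.csv``); the
    ``iop_corvis`` column carries the generator's true pressure so the
    validation tooling can be exercised against a known reference.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth_rows, cov_rows = [], []
    for eye in eyes:
        eye_id = eye.sequence.meta.id
        write_sequence_csv(eye.sequence, out_dir / f"{eye_id}.csv")
        eye.modal_truth.write_csv(out_dir / f"{eye_id}.modal_truth.csv")
        cfg = eye.config
        truth_rows.append(
            {"id": eye_id, "iop": cfg.iop, "cct": cfg.cct, "age": cfg.age,
             "misalign": cfg.misalign, "seed": cfg.seed,
             "a1_true": eye.a1_true, "a2_true": eye.a2_true}
        )
        cov_rows.append(
            {"id": eye_id, "age": cfg.age, "cct_um": cfg.cct,
             "radius_mm": cfg.radius,
             "a1t_ms": (eye.a1_true or 0) * cfg.dt_ms,
             "iop_corvis": cfg.iop, "iop_pach": cfg.iop}
        )
    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.csv", index=False)
    cov = pd.DataFrame(cov_rows)
    cov.to_csv(out_dir / "covariates.csv", index=False)
    return cov


def render_frame_image(
    frame: ContourFrame,
    pixel_size: float = 0.02,
    thickness_px: int = 10,
    noise_sd: float = 0.0,
    blur_sigma: float = 1.0,
    pad_px: int = 12,
    rng: Optional[np.random.Generator] = None,
) -> GrayscaleFrame:
    """Rasterize a contour as a bright corneal band on a dark background.

    The band's top edge follows the anterior contour; ``truth_z_px`` records
    the true (sub-pixel) edge row per column for segmentation tests.
    ``noise_sd`` adds speckle as a fraction of the peak intensity.
    """
    from scipy.ndimage import gaussian_filter

    if thickness_px <= 0:
        raise ConfigError("band thickness must be at least 1 pixel")
    if rng is None:
        rng = np.random.default_rng(0)
    x0 = frame.x.min()
    n_cols = int(np.floor((frame.x.max() - x0) / pixel_size)) + 1
    x_cols = x0 + np.arange(n_cols) * pixel_size
    z_true = np.interp(x_cols, frame.x, frame.z)
    z_px = (z_true - frame.z.min()) / pixel_size + pad_px
    n_rows = int(np.ceil(z_px.max() + thickness_px + pad_px))

    rows = np.arange(n_rows, dtype=float)[:, None]
    top, bottom = z_px[None, :], (z_px + thickness_px)[None, :]
    # anti-aliased coverage of each pixel row by the [top, bottom] band
    img = np.clip(np.minimum(rows + 1.0, bottom) - np.maximum(rows, top), 0.0, 1.0)
    img = gaussian_filter(img, sigma=blur_sigma)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd * img.max(), size=img.shape)
    img = np.clip(img, 0.0, None)
    return GrayscaleFrame(
        pixels=img,
        pixel_size=pixel_size,
        frame_index=frame.frame_index,
        truth_z_px=z_px,
        truth_x_mm=x_cols,
    )
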