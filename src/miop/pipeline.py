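"""End-to-end orchestration: contour input -> modal profiles -> mIOP.

`run_miop` executes the full estimation chain for one eye and `run_validation`
repeats it across a cohort directory, then runs the agreement and screening
statistics against a covariate table.  Both are deterministic for fixed
inputs and configuration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats, deformation_features as feat
from .contour_core import DeformationSequence, read_sequence_csv, smooth_contour
from .errors import ConfigError, MiopError, NoApplanation
from .image_segmentation import QualityThresholds, quality_check
from .modal_decomposition import ModalProfileMatrix, decompose_sequence

__all__ = ["PipelineConfig", "RunReport", "run_miop", "run_validation"]


@dataclass
class PipelineConfig:
    smoothing: float = 0.0  # spline roughness penalty; 0 interpolates
    max_order: int = 5
    convention: str = "normalized"
    deflection_mode: str = "from_reference"
    applanation_aperture_mm: float = 1.0
    kappa_tol: float = 0.005
    quality: QualityThresholds = field(default_factory=QualityThresholds)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        quality = QualityThresholds(**raw.pop("quality", {}))
        return cls(**raw, quality=quality)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class RunReport:
    """Per-eye result: mIOP is present iff quality control passed and the
    M4 ratio was finite."""

    id: str
    qc_passed: bool
    miop: Optional[float] = None
    ratio_rising_4: Optional[float] = None
    a1: Optional[int] = None
    a2: Optional[int] = None
    warnings: List[str] = field(default_factory=list)
    features: Dict[str, float] = field(default_factory=dict)
    modal_profile_path: Optional[str] = None

    def to_dict(self) -> dict:
        return asdict(self)


def _feature_vector(mp: ModalProfileMatrix, app) -> Dict[str, float]:
    table = feat.primary_features(mp, app)
    vec: Dict[str, float] = {}
    for mode, row in table.iterrows():
        for name, value in row.items():
            vec[f"m{mode}_{name}"] = float(value)
    ratios = feat.secondary_ratios(mp, app)
    for n in ratios.rising:
        vec[f"m{n}_ratio_rising"] = ratios.rising[n]
        vec[f"m{n}_ratio_down"] = ratios.down[n]
    return vec


def run_miop(
    source,
    config: PipelineConfig = PipelineConfig(),
    out_dir: Optional[Path] = None,
) -> RunReport:
    """Estimate mIOP for one eye from a contour CSV or a DeformationSequence.

    Pipeline: (read) -> quality control -> smoothing-spline fit ->
    reference-circle fit -> angular deflection profiles -> Legendre
    decomposition (orders 0..5) -> applanation detection -> AUC-ratio
    features -> mIOP.  Intermediates are persisted when ``out_dir`` is given.
    """
    if isinstance(source, DeformationSequence):
        seq = source
    else:
        with warnings.catch_warnings(record=True):
            warnings.simplefilter("always")
            seq = read_sequence_csv(source)
    report = RunReport(id=seq.meta.id or "eye", qc_passed=False)

    qc = quality_check(seq, config.quality)
    report.qc_passed = qc.passed
    if not qc.passed:
        reason = "truncated sequence" if qc.truncated else f"{qc.n_bad} bad frames"
        report.warnings.append(f"quality control failed: {reason}")
        return report

    if config.smoothing > 0:
        smoothed = DeformationSequence(
            frames=[smooth_contour(f, config.smoothing) for f in seq.frames],
            dt_ms=seq.dt_ms,
            meta=seq.meta,
        )
    else:
        smoothed = seq  # lam=0 interpolates exactly: identity on the grid
    mp = decompose_sequence(
        smoothed,
        N=config.max_order,
        convention=config.convention,
        deflection_mode=config.deflection_mode,
    )

    app = None
    try:
        app = feat.detect_applanation_frames(
            seq, config.applanation_aperture_mm, config.kappa_tol
        )
        report.a1, report.a2 = app.A1, app.A2
    except NoApplanation as exc:
        report.warnings.append(f"applanation detection: {exc}")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            if app is not None:
                report.features = _feature_vector(mp, app)
                ratio = report.features["m4_ratio_rising"]
            else:
                row = mp.mode(4)
                ratio = feat.auc(row, 1, mp.n_frames) / feat.auc(
                    row, *feat.RISING_WINDOW
                )
            if np.isfinite(ratio):
                report.ratio_rising_4 = float(ratio)
                report.miop = feat.miop(ratio)
        except MiopError as exc:
            report.warnings.append(f"feature extraction: {exc}")
        report.warnings.extend(str(w.message) for w in caught)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        profile_path = out_dir / f"{report.id}.modal_profile.csv"
        mp.write_csv(profile_path)
        report.modal_profile_path = str(profile_path)
        with open(out_dir / f"{report.id}.report.json", "w") as fh:
            json.dump({"config": config.to_dict(), **report.to_dict()}, fh,
                      indent=1, default=float)
    return report


def run_validation(
    cohort_dir,
    covariates_csv,
    config: PipelineConfig = PipelineConfig(),
    out_dir: Optional[Path] = None,
) -> dict:
    """Run the estimator over a cohort and compute validation statistics.

    Expects one contour CSV per eye in ``cohort_dir`` (truth/covariate
    tables are ignored when globbing) and a covariate CSV with columns
    id, age, cct_um, radius_mm, a1t_ms, iop_corvis, iop_pach.  Returns a
    dict with the per-eye table, univariate fits of mIOP against each
    covariate, Bland-Altman agreement against the reference IOPs, and the
    screening ranking; writes them as CSV when ``out_dir`` is given.
    """
    cohort_dir = Path(cohort_dir)
    skip = {"truth", "covariates"}
    paths = sorted(
        p for p in cohort_dir.glob("*.csv")
        if p.stem not in skip and not p.stem.endswith(".modal_truth")
        and not p.name.endswith(".meta.json")
    )
    if len(paths) < 3:
        raise ConfigError("validation needs at least 3 eyes")
    covs = pd.read_csv(covariates_csv)
    if "id" not in covs.columns:
        raise ConfigError("covariate table must have an id column")

    reports = [run_miop(p, config) for p in paths]
    rows = []
    for r in reports:
        rows.append({"id": r.id, "miop": r.miop,
                     "ratio_rising_4": r.ratio_rising_4,
                     "a1": r.a1, "a2": r.a2, "qc_passed": r.qc_passed,
                     **r.features})
    eyes = pd.DataFrame(rows)
    merged = eyes.merge(covs, on="id", how="inner")
    if len(merged) < 3 or merged["miop"].notna().sum() < 3:
        raise ConfigError("fewer than 3 eyes align between cohort and covariates")
    ok = merged[merged["miop"].notna()]

    fits = {}
    for cov in ("age", "cct_um", "radius_mm", "a1t_ms", "iop_corvis"):
        if cov in ok.columns and np.var(ok[cov].to_numpy(dtype=float)) > 0:
            fits[cov] = cohort_stats.univariate_fit(
                ok[cov].to_numpy(dtype=float), ok["miop"].to_numpy(dtype=float)
            )
    agreement = {}
    for ref in ("iop_corvis", "iop_pach"):
        if ref in ok.columns:
            agreement[ref] = cohort_stats.bland_altman(
                ok["miop"].to_numpy(dtype=float), ok[ref].to_numpy(dtype=float)
            )
    feature_cols = [c for c in eyes.columns
                    if c.startswith("m") and eyes[c].notna().all()]
    screening = cohort_stats.screen_candidates(
        ok[["id"] + feature_cols] if "id" in ok.columns else ok, covs,
        feature_columns=feature_cols,
    )

    results = {"eyes": merged, "fits": fits, "agreement": agreement,
               "screening": screening}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        merged.to_csv(out_dir / "eyes.csv", index=False)
        screening.to_csv(out_dir / "screening.csv", index=False)
        with open(out_dir / "validation.txt", "w") as fh:
            for cov, fit in fits.items():
                fh.write(
                    f"mIOP ~ {cov}: beta={fit.slope:.5g} r={fit.pearson_r:.4f} "
                    f"p={fit.p_slope:.3g} (n={fit.n})\n"
                )
            for ref, ba in agreement.items():
                fh.write(
                    f"Bland-Altman mIOP vs {ref}: mean diff {ba.mean_diff:.3f} "
                    f"mmHg, LOA [{ba.loa_low:.3f}, {ba.loa_high:.3f}]\n"
                )
    return results
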