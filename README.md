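# miop — modal-analysis intraocular pressure estimation

`miop` estimates intraocular pressure (IOP) from the dynamics of air-puff
corneal deformation, as recorded by a high-speed Scheimpflug tonometer
(140 cross-sectional frames over ~32 ms). It is aimed at researchers in
ocular biomechanics and tonometry who want a physically interpretable,
thickness-independent pressure index, and at anyone who needs a fully
synthetic, ground-truthed test bed for corneal deformation analysis.

## The method

Each frame's anterior corneal contour is mapped to a deflection profile
u(θ) over the signed angle θ from the apex (|θ| ≤ θ_R ≈ 0.6 rad) and
expanded on Legendre polynomials in s = θ/θ_R:

    u(s, tᵢ) = Σₙ Pₙ(s) aₙ(tᵢ),        aₙ(tᵢ) = (2n+1)/2 ∫₋₁¹ u(s, tᵢ) Pₙ(s) ds

truncated at n = 5. The time series aₙ(tᵢ) across the 140 frames are the
*modal profiles*: M₀ captures whole-eye movement, odd modes capture puff
misalignment and rotation, and the symmetric bending modes M₂ and M₄ carry
the pressure response. Because the air-puff loading profile is identical in
every exam, the area under a modal profile acts as the work done on that
modal shape, and ratios of such areas cancel the amplitude scale set by
corneal thickness and stiffness. The estimator uses a single feature, the
**M₄ ratio** — the total AUC (frames 1–140) of the M₄ profile divided by its
rising-phase AUC (frames 24–40) — in a linear calibration:

    mIOP = 0.586 × M₄ ratio + 8.2698   [mmHg]

Candidate features are screened with the performance score
½(r_IOP-Corvis + r_IOP-Pach) − ⅓(r_age + r_radius + r_CCT), which rewards
correlation with reference IOP readings and penalizes correlation with the
classic confounders.

The package implements the full chain: contour CSV I/O and optional
segmentation of rendered grayscale frames, smoothing-spline fitting,
reference-circle geometry, Legendre decomposition, applanation detection
from central curvature, AUC-ratio features, the mIOP model, cohort
statistics (univariate fits with the extra-sum-of-squares F test,
Bland–Altman agreement, paired pre/post changes, feature screening), and a
mode-space simulator that generates 140-frame sequences with exact modal
ground truth.

## Worked example

Simulate one eye (true IOP is drawn per eye and recorded in `truth.csv`)
and estimate its pressure:

```
$ miop simulate --n 1 --seed 7 --noise-sd 0.002 --out demo
wrote 1 eyes to demo
$ miop estimate --input demo/sim0001.csv
{
 "id": "sim0001",
 "qc_passed": true,
 "miop": 10.444630532036928,
 "ratio_rising_4": 3.71131490108691,
 "a1": 32,
 "a2": 113,
 ...
}
```

Quality control passed, the first/second applanations were detected at
frames 32 and 113, the M₄ ratio is 3.71, and the calibrated estimate is
0.586 × 3.71 + 8.2698 ≈ 10.4 mmHg. On a cohort the validation command
reports how the estimate relates to the recorded covariates and reference
readings:

```
$ miop simulate --n 8 --seed 7 --noise-sd 0.002 --out demo8
$ miop validate --cohort demo8 --covariates demo8/covariates.csv
mIOP ~ age: beta=0.030192 r=0.6002 p=0.116
mIOP ~ cct_um: beta=0.0022836 r=0.1326 p=0.754
mIOP ~ a1t_ms: beta=3.7929 r=0.7358 p=0.0375
mIOP ~ iop_corvis: beta=0.16931 r=0.9689 p=7.37e-05
Bland-Altman vs iop_corvis: mean -5.597 mmHg, LOA [-10.686, -0.509]
Bland-Altman vs iop_pach: mean -5.597 mmHg, LOA [-10.686, -0.509]
```

The estimate tracks the generator's true pressure tightly (r = 0.97,
p < 10⁻⁴) while staying nearly independent of corneal thickness — the
self-calibration property the ratio construction is designed for. (The
fixed negative offset against the reference column reflects the simulator's
uncalibrated ratio scale; see `docs/methods.md`.)

The same functionality is available as a library:

```python
from miop import SimConfig, simulate, run_miop
eye = simulate(SimConfig(iop=16.0, noise_sd=0.002, seed=1))
report = run_miop(eye.sequence)
print(report.miop, report.ratio_rising_4)
```

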