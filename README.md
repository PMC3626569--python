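# musclemt

Automatic muscle-thickness (MT) estimation for longitudinal B-mode
ultrasound of skeletal muscle.

Muscle thickness — the distance between the superficial and deep
aponeuroses — tracks muscle activity during contraction and is a standard
measure in musculoskeletal ultrasound (sonomyography). Reading it manually
with an on-screen caliper, frame by frame, is slow and subjective; the
obstacle to automating it is speckle, the multiplicative interference noise
of coherent imaging. `musclemt` implements an automatic four-step pipeline
for researchers who need per-frame MT from image sequences:

1. **Enhancement** of the bright (hyperechoic) tubular structures, by one of
   two methods:
   - *Gabor filtering*: block-wise orientation field θ(x) from the gradient
     structure tensor, a ridge-frequency map f(x), and an even-symmetric
     Gabor kernel tuned to (θ, f) per block — applied only where the
     orientation coherence exceeds a reliability threshold (default 50%);
   - *MVEF* (multiscale vessel enhancement filtering): Hessian eigenvalues
     |λ₁| ≤ |λ₂| at Gaussian scales σ, combined into the vesselness
     V = exp(−R_B²/2β²)·(1 − exp(−S²/2c²)) for λ₂ < 0, with
     R_B = λ₁/λ₂ and S = √(λ₁²+λ₂²), maximized over scales.
2. **Binarization** (Otsu) into an edge map.
3. **Revoting Hough Transform (RVHT)**: find the global (ρ, θ) accumulator
   peak, delete edge pixels near that line, re-accumulate, repeat.
4. **Thickness**: among the detected lines, the pair with maximum mean
   distance is taken as the aponeuroses; MT is the mean middle-line distance
   between them, in mm via the scanner calibration (mm/pixel).

MT time series are median-smoothed, with frames flagged when the raw value
departs from the smoothed one by more than 0.5 mm. The package also ships
the reliability statistics used to evaluate such measurements —
ICC(A,1) with its F-based confidence interval, SEM = s·√(1−ICC),
MDC = SEM·1.96·√2, Bland–Altman limits of agreement, squared Pearson
correlation — and a synthetic speckle-phantom generator with exact
ground-truth geometry so the whole pipeline is testable end to end.

## Worked example

Measure a six-frame synthetic sequence whose true thickness follows a known
trajectory (0.1 mm/pixel calibration, speckle with 30% dispersion):

```python
from musclemt import PhantomConfig, PipelineConfig, generate_sequence, run_pipeline

cfg = PhantomConfig(speckle_scale=0.3)
frames, truths = generate_sequence(cfg, 6, [15.0, 15.2, 15.5, 15.3, 15.1, 14.9], seed=42)
df, n_failures = run_pipeline(PipelineConfig(method="mvef"), frames)
print(df[["frame", "mt_mm", "rho1", "theta1_deg", "votes1", "outlier", "status"]])
```

```
 frame  mt_mm  rho1  theta1_deg  votes1  outlier status
     0   15.0 103.0        89.0     384    False     ok
     1   15.2 103.0        89.0     384    False     ok
     2   15.5 104.0        89.0     385    False     ok
     3   15.3 103.0        89.0     384    False     ok
     4   15.0 104.0        89.0     385    False     ok
     5   14.8 104.0        89.0     385    False     ok
```

`mt_mm` is the per-frame thickness (true values 15.0, 15.2, 15.5, 15.3,
15.1, 14.9 mm — every frame recovered within 0.1 mm); `(rho1, theta1_deg,
votes1)` is the detected superficial aponeurosis line in Hough normal form
with its vote count; `outlier` marks frames disagreeing with the median-
smoothed series by more than 0.5 mm; no frame failed detection.

The same workflow is available from the shell:

```sh
musclemt phantom --out frames/ --frames 6 --seed 42
musclemt measure --in frames/ --method mvef --spacing-mm 0.1 --out results.csv
musclemt stats --in ratings.csv --group-col subject --out report.csv
```

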