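# Methods

This note documents the models, parameter choices and numerical conventions
behind `musclemt`, and what the synthetic-phantom experiments do and do not
establish about clinical images.

## Measurement model

A longitudinal sonogram of a muscle belly shows the superficial and deep
aponeuroses as bright, quasi-horizontal bands and the muscle fascicles /
fibroadipose septa as weaker oblique streaks, all corrupted by speckle.
The pipeline assumes the aponeuroses are (a) well approximated by straight
lines over the field of view and (b) after enhancement, the two most
vote-rich lines in the Hough accumulator. Thickness is defined as the mean
*middle-line* distance between the two detected centerlines: for each
column x the rows y₁(x), y₂(x) of the lines are evaluated, and

MT = mean over x of |y₁(x) − y₂(x)| · |sin((θ₁+θ₂)/2)|,

i.e. the vertical separation projected perpendicular to the mean
orientation. Columns where a line leaves the image are excluded (a warning
is logged when fewer than half remain). This definition differs from a
manual border-to-border caliper reading by roughly the aponeurosis wall
thickness (~1.4 mm on typical gastrocnemius images); the bias is inherent
and deliberately not corrected. A near-vertical detected line (|sin θ| <
1e−6) raises a geometry error: it can only be a detection failure.

## Enhancement

**Gabor.** The classic ridge-pattern construction: per 16×16 block, the
gradient structure tensor gives the dominant orientation
θ = ½·atan2(2Gxy, Gxx−Gyy) + π/2 (mod π) and the coherence
√((Gxx−Gyy)² + 4Gxy²)/(Gxx+Gyy) ∈ [0,1] (defined as 0 for constant
blocks). The ridge frequency is the reciprocal of the mean peak spacing of
the block's x-signature (intensity averaged along the ridge direction,
sampled across it); blocks with fewer than two peaks or a period outside
[2, 4·block] px are invalid. Filtering uses an even-symmetric, DC-free
Gabor kernel (σx = σy = 4 px, truncated at 3σ) tuned to the block's (θ, f);
blocks with coherence below the reliability threshold (default 0.5) are
zeroed — this is what suppresses incoherent speckle background. Reliable
blocks with no valid frequency (a lone aponeurosis ridge is strong but
aperiodic) borrow the median frequency of the valid blocks. Orientation
and frequency are block-constant; (θ, f) pairs are quantized to 16
orientations and integer periods so each distinct kernel costs one
full-image FFT convolution. Consequence of the gate worth knowing: under
very heavy speckle (dispersion ≳ 0.8) no block reaches 50% coherence and
the output is empty — the gate reports "nothing reliable" rather than
guessing.

**MVEF.** Hessian estimated by convolution with Gaussian second-derivative
kernels, scale-normalized by σ² (γ = 1). The image mean is removed first:
truncated derivative kernels do not sum exactly to zero, and the response
must be invariant to constant offsets. Eigenvalues are ordered |λ₁| ≤ |λ₂|;
only λ₂ < 0 (bright structure) responds. Defaults: β = 0.5 (standard
blobness weight); c set per scale to half the maximum Frobenius norm of the
Hessian over the image (the common auto-tuning); scales {1.5, 3, 5, 7} px,
bracketing aponeurosis half-thicknesses at typical resolutions. All are
config-exposed and logged. No dark-structure mode and no eigenvector
output: the scalar response is all the Hough stage needs.

## Binarization

Otsu's 256-bin between-class-variance threshold, applied per frame
independently; both enhancement outputs are strongly bimodal (structure vs
suppressed background), which is why no morphological cleanup is needed. A
constant image yields an empty edge map with a warning. A fixed-level mode
exists for reproducibility experiments.

## RVHT

The accumulator uses θ bins at i·1° for i ∈ [0, 180), ρ bins at 1 px
centered on integers over [−⌈D⌉, ⌈D⌉] (D = image diagonal); every on-pixel
votes in exactly one ρ bin per θ bin (nearest bin, half-up), so total votes
= n_on × n_θ exactly — an integer identity the tests assert. Peak ties
break to the smallest θ bin, then the smallest ρ bin. After each peak,
pixels within 3 px perpendicular distance are removed (≈ the aponeurosis
band half-thickness) and the accumulator is recomputed from scratch from
the pruned map — full re-accumulation matches the algorithm's definition
and avoids the aliasing of accumulator subtraction. No sub-bin peak
refinement: the bin-center line is returned. With the default of two
detected lines, "the first two lines" and "the maximum-distance pair"
coincide; for n_lines > 2 the maximum-distance rule selects the pair, with
ties broken by combined vote count.

A quantization effect to be aware of: a band several pixels thick supports
the same maximal vote count over a couple of adjacent θ bins (a line tilted
by 1–2° still threads the band), so the detected orientation can sit 1–2°
off horizontal while the row position stays sub-pixel accurate. The effect
on MT is second-order (cos 2° ≈ 0.9994).

## Time series

The smoothed series is a centered running median (default window 5; the
window shrinks at the edges); a frame is flagged as an outlier when
|raw − smoothed| > 0.5 mm. The threshold is the conventional flagging
level for MT transitions; the window length is the implementer's choice
and config-exposed.

## Reliability statistics

ICC(A,1) — single-measure, absolute-agreement, two-way model — is computed
from the ANOVA mean squares, with the standard F-based confidence interval
for that coefficient; the implementation is cross-checked in the tests
against an independently coded ANOVA oracle (statsmodels OLS) and against
pingouin. SEM = s_x·√(1−ICC), MDC = SEM·1.96·√2. When reproducing printed
summary tables, MDC is computed from the SEM rounded to two decimals
(`round_sem=True`), because printed MDCs are consistent with rounded-SEM
inputs (e.g. SEM 0.35 → MDC 0.97); full precision is the default
otherwise. Bland–Altman uses the sample SD of the differences and 1.96
limits. The P-P plot helper is visual only; no normality statistic is
computed. All statistics treat their inputs as already-calibrated mm and
take no position on pixel spacing.

## Synthetic phantom

The generator renders: two bands with Gaussian cross-profile (σ =
halfwidth/2, so ridge filters see realistic crests rather than step edges)
whose centerlines are exactly known straight lines; oblique bright streaks
(rectified sinusoid) strictly between the bands, emulating fibroadipose
septa; and multiplicative speckle — each pixel scaled by an independent
Gamma factor with unit mean and shape 1/scale² (a first-order surrogate for
fully developed speckle with one dispersion dial). Defaults chosen as
typical of a longitudinal gastrocnemius view: band intensity 0.9 over
background 0.2 (aponeuroses are markedly brighter than muscle tissue),
fascicle streaks at 15° (common pennation range) with contrast 0.15 (septa
are only mildly hyperechoic), speckle dispersion 0.3, calibration
0.1 mm/px (no reference calibration exists; it is configurable).
Coordinates are 0-based with rows increasing downward, so superficial =
smaller row. Ground truth records the band lines in (ρ, θ) form and the
mean vertical separation as mt_px.

What the phantom does **not** emulate: acoustic point-spread blur,
depth-dependent attenuation/TGC, curved aponeuroses, subcutaneous tissue
layers, and spatially correlated speckle. Passing the phantom experiments
therefore demonstrates that the algorithm chain is implemented correctly
and is robust to uncorrelated multiplicative noise and oblique distractor
texture — not that it meets any particular accuracy on clinical images.

## Experiment sizes

The end-to-end recovery experiments use 256×192 px phantoms: a 50-point
thickness sweep over 80–200 px noise-free (both enhancement methods,
median |error| ≤ 2 px and both aponeuroses identified as the two detected
lines in every frame), 20 seeds × 5 thickness levels at speckle 0.3 (mean
|error| ≤ 3 px per method), and a 20-seed ablation at speckle 0.6
comparing recovery with MVEF enhancement against binarizing the raw frame
(enhanced ≥ raw). These sizes give stable medians/means while keeping the
whole suite fast; the phantom geometry, not the sample count, is the
limiting factor on what they can show.

## Known limitations

- The middle-line MT definition carries the documented positive bias
  against border-to-border manual readings; no correction is applied.
- The Gabor path degrades abruptly once no block passes the coherence
  gate; MVEF is the robust (and much cheaper) default.
- Straight-line aponeurosis model: curved or interrupted aponeuroses
  violate the Hough assumption.
- The Hough θ quantization (1°) bounds orientation accuracy; MT accuracy
  is set mainly by the ρ step (1 px).
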