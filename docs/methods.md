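# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `pentafluct`. All quantitative claims here are the ones
the test suite and `scripts/acceptance.py` themselves compute.

## The measurement problem

Pentameric receptors in a cell membrane exist both as single complexes and
as bright clusters of many complexes. The package quantifies *single
pentamer* properties — mobility, stoichiometry, co-assembly, channel
current — from fluorescence image series and patch-clamp traces, with
cluster pixels masked out of every fluctuation estimate. Because no raw
cell data ships with the package, every estimator is validated closed
loop: synthetic scenes with known ground truth are rendered through the
acquisition geometry being emulated and the analysis must return the
truth.

## Synthetic scenes (`synthgen`)

**Brownian membrane scenes.** Particles diffuse on a periodic 2D box; each
axis increment over Δt is Gaussian with SD √(2DΔt). The box side is twice
the rendered field of view (4× the area), so wrap-around cannot deplete or
correlate the field — the field sits centered with a margin much larger
than any PSF cutoff. Clusters are a second population with their own
diffusion constant, a Gaussian-blob profile of radial SD `radius` and a
peak brightness multiple of the single-pentamer brightness. The default
cluster used in the recovery experiments (peak 40× a single pentamer,
radius 0.25 µm, D = 0.01 µm²/s) corresponds to an aggregate of a few
hundred pentamers, matching the observation that clustered regions hold
receptors at thousands per µm² while the diffuse pool sits at tens per
µm².

**Confocal raster rendering.** Pixels are visited in row-major order;
particle positions advance at line granularity by default (a per-pixel
high-accuracy mode exists for small oracle scenes). The expected count at
a pixel is τ_p × [background + Σ ε·exp(−2r²/ω_r²)] with everything in kHz;
realized counts are Poisson. At D ≤ 1 µm²/s the RMS motion within one
4.92 ms line is ≲140 nm, and the only correlation the line-granularity
approximation misses is the µs-scale decay along the fast axis, a <1%
effect at these settings (the per-pixel mode backs this in tests).

**Camera rendering.** Each frame splats an integrated 2D Gaussian PSF
(σ = ω_r/2) per particle, sampled mid-exposure, times the exposure, plus
background; noise is Poisson plus additive Gaussian read noise. Dual-color
scenes alternate excitation within the frame (green at t+10 ms, red at
t+30 ms of an 80 ms frame, 20 ms exposures each): a fraction q of
particles carries both color species, the remainder splits evenly into
single-color pools, and each carried fluorophore matures with probability
p_m. A single-channel rendering images *all* particles — the species
split is a dual-color concept. EMCCD excess noise is not modeled: it
rescales amplitudes but not correlation decay times, and camera
brightness is treated as uncalibrated throughout.

**Bleaching traces.** Spot traces are unit intensity × surviving labels
plus Gaussian noise; each label bleaches once at a geometric frame
(no blinking), so the true step count equals the initial label count.

**Gating traces.** Two-state continuous-time Markov gating; open
probability k_open/(k_open+k_close).

All generators are deterministic given (parameters, seed); trajectories
replay lazily from their seed so raster rendering never materializes the
full line-resolved position history.

## Masking (`masking`)

A pixel is excluded when the boxcar mean of its ~5×5 neighborhood is at
least k = 3 times the mean intensity of all currently included pixels of
the whole preprocessed series. Because bright clusters inflate that
reference mean, one pass under-excludes; the rule is iterated to
convergence (≤10 passes; the excluded set grows monotonically as the
reference falls). Grids are then smoothed with a 3×3 median (majority)
filter. Dynamic mode thresholds each frame; static mode thresholds the
time average. Boxcar windows shrink at the borders rather than
zero-padding, so edges are not artificially excluded. Increasing k never
excludes more pixels; re-running on an already-masked series is a no-op —
both properties are tested.

## RICS (`rics`)

The chain is: moving-average correction (ΔF = 1, window truncated at the
ends, global mean restored exactly) → masked spatial autocorrelation
(every lag normalized by its count of both-included pixel pairs; FFT path
equal to the direct sum to 1e-10) → weighted fit of

G(ξ,ψ) = γ/N · (1+4D|ξτ_p+ψτ_l|/ω_r²)⁻¹ ·
exp(−δr²(ξ²+ψ²)/(ω_r²+4D|ξτ_p+ψτ_l|)) + G_∞

with γ = 2^(−3/2) fixed, the (0,0) lag excluded (shot noise), default fit
radius 16 px along the fast axis and 8 lines, and per-lag weights from
the across-frame SD.

**The offset term G_∞.** The moving-average correction is a temporal
high-pass: concentration modes of wavelength λ relax over λ²-scale times,
and modes slower than the ~3-frame window are subtracted. Over the fit
window this removes a nearly flat pedestal from the correlation surface;
fitting the bare model then biases D low by tens of percent at these
geometries, while co-fitting a constant absorbs the pedestal. The offset
is on by default and reported.

**Brightness.** ε = F/N with F the masked mean intensity in kHz
(counts/τ_p). The moving-average correction multiplies the variance of
frame-uncorrelated fluctuations by 2ΔF/(2ΔF+1), so the fitted N is
deflated by the same factor before the division (amplitude bias factor
(2ΔF+1)/2ΔF = 3/2 at ΔF = 1; overridable, logged). This is the
frame-uncorrelated limit of the correction; the frame-correlated case
would need the full filter transfer function and is intentionally not
guessed. Absolute ε carries the usual γ-convention ambiguity; all
stoichiometry statements rest on ε *ratios* (the closed-loop pentamer vs
monomer ratio test recovers 5.0).

**Recovery accuracy.** With the cluster population present and
dynamically masked, the 10-seed mean D at the published raster geometry
comes back ~10–13% high (cluster Gaussian tails survive the core
exclusion and interact with the offset term); without clusters the bias
is ~–6%. Both are within the 15% band the acceptance suite enforces, and
the residual bias is reported here rather than tuned away.

## TICS / TICCS (`tics`)

Frame detrending equalizes frame means; per-pixel fluctuation traces are
correlated by zero-padded FFT with unbiased (T−m) normalization and
per-pixel normalization by the product of temporal means; curves average
with equal weight over included pixels (95% CI across pixels). Per-frame
masks reduce to their across-frame intersection — a dynamic mask cannot
yield gap-free pixel traces. The fit G(τ) = A_D(1+4Dτ/ω_r²)⁻¹ + A_0 runs
over lags 1..12 (τ = 0 excluded: shot/read noise).

The model treats each pixel as a point detector. At 150 nm pixels with a
300 nm waist this biases recovered D low by ~10% (the acceptance band is
20%); an analytic pixel-integrated oracle in the tests shows the bias
shrinking below 5% at 25 nm pixels. Rel.CC = G_CCF(0)/mean(G_ACF1(0),
G_ACF2(0)) with G(0) = A_D + A_0 from each fit; negative CCF amplitudes
floor at 0. Alternating excitation samples the two channels 40 ms apart,
which deflates the measured Rel.CC by ~(1+4DΔt/2/ω_r²)⁻¹ ≈ 10% at these
conditions — visible in the closed-loop comparison against the
trajectory-label oracle and left uncorrected, as in the emulated
acquisition.

## Pearson colocalization (`colocalization`)

Channels are averaged over the first 5 frames; ρ(ξ,ψ) uses both-included
pixel pairs in the numerator and the *unshifted* included-pixel SDs in
the denominator (as the estimator is defined), so off-center values may
slightly exceed a per-shift-renormalized coefficient. ρ(0,0) equals the
textbook Pearson coefficient to 1e-12 on a full mask.

## Step counting (`stepcount`)

Spot candidates are local maxima of the first-frames average with
δF/F ≥ 20% over the local background (mean of an 11×11 surround excluding
the central 5×5 — the exact background definition of the original
locator tool is unpublished, so it is parameterized, not asserted).
Overlapping 5×5 windows are discarded wholesale; traces are 3×3 sums.

Step localization is iterative changepoint insertion minimizing a Schwarz
criterion with the penalty inflated 2× (the bare penalty over-segments
long traces because the extreme-order statistic of a spurious split also
grows like ln N; the factor plays the role of a step-finder sensitivity
setting and is validated on ground-truth staircases, exactly recovered
whenever all dwells ≥ 3 frames). The acceptance filters then apply
verbatim: every dwell ≥ 3 frames; every downward step within 60% of the
*median* step amplitude (median preferred over mean for robustness;
configurable); step SNR ≥ 2 against the pooled SD of the two adjacent
dwells; no upward steps and the final level lowest. Fields with <10%
accepted traces are dropped before histogramming.

The step-count models, with n = 5 and x the observed steps:

B(x) = A·Binom(x; n, p_m) + (1−A)·Binom(x; 2n, p_m)
B_het(x) = H·B(x; n…) + (1−H)·B(x; het…)

Spots with x = 0 are unobservable, so the pmf renormalizes over x ≥ 1 for
fitting (switchable). Fits are least squares of expected counts with
parameters bounded in [0,1]; χ² uses occupied bins with
dof = occupied − free − 1. The mixture keeps one type per spot: the
overlap branch doubles the order within a type, and mixed-type double
spots are outside the model by construction.

**Order discrimination is weak by design of the experiment.** At 301
spots with p_m = 0.47, A = 0.88 and a 36% heteromer fraction, the
asymptotic χ² advantage of the true labeled order 3 over orders 2 and 4
is ≈1.4 — the same magnitude as its sampling noise — so the true order
tops the χ² ranking in only about half of replicate datasets (the
neighbouring orders fit almost as well, mirroring the near-tied
goodness-of-fit values such data produce). The tests therefore assert a
plurality for the true order; the recovered heteromer *fraction* at the
true order is accurate to a few percentage points.

## Single-channel currents (`singlechannel`)

The digital Gaussian low-pass defines its cutoff at −3 dB
(σ_t = √(ln 2)/2πf_c; the emulated acquisition does not state its
convention). The upstream 2.9 kHz hardware filter is not emulated — it is
invisible at a 100 Hz analysis bandwidth. Window analysis fits a double
Gaussian to the sample histogram of a <1 s window; the component nearer
zero is the baseline and the mixture is flagged collapsed when the means
sit closer than 1.5× the wider component. Grouping sorts window means and
splits greedily at a 1 pA default tolerance (the emulated analysis gives
no number; the greedy sorted scan is provably minimal in group count for
1D data and is checked against exhaustive enumeration). Window selection
is manual by design; `propose_windows` is a clearly-marked convenience
that flags variance bursts.

## Problem sizes in the validation runs

The recovery experiments default to scaled-down acquisitions chosen as
the package's own compromise between statistical power and runtime on one
CPU: RICS uses 25 frames of 256×256 px (the emulated study records 100),
TICS 200 frames of 128×128 px (vs 400 of 256×256), 10 seeds per
condition. The estimator code paths are identical at any size, and the
tolerances asserted are the ones quoted above, not loosened for size.

## Known limitations

* Absolute molecular brightness and absolute N carry the focal-volume
  shape-factor convention; only ratios are interpreted.
* The TICS model ignores finite pixel size and TIRF's uniform lateral
  excitation; recovered slow-diffusion D is ~10% low at 150 nm pixels.
* The masked RICS chain retains a ~10% high bias on D when bright
  clusters are present and masked, from cluster tails below threshold.
* The synthetic membrane is a homogeneous periodic plane: no confinement,
  binding, photobleaching during fluctuation imaging, stage drift or
  vignetting. Passing recovery tests demonstrates estimator correctness
  under the stated model, not robustness to every cell-biological
  artifact.
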