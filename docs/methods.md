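# Methods

This package quantifies the liquid-like behaviour of nuclear protein
condensates (the motivating system is SS18, a BAF-complex subunit that forms
tyrosine-IDR-driven droplets in mouse embryonic stem cell nuclei) together
with the tabular statistics that accompany such a study: pooled CRISPR-screen
count normalization and chromatin-site relocation. Every analysis is
developed and validated against a synthetic-data module that generates the
same observables with known ground truth.

## Models

### FRAP recovery

A bleached circular region refills by molecular exchange. The normalized
intensity (percent of the pre-bleach mean, background-subtracted) follows a
single exponential,

    I(t) = i0 + (P − i0) (1 − e^(−t/τ)),   t ≥ 0 at the bleach frame,

with three free parameters: the immediate post-bleach level `i0` (absorbs
incomplete bleaching), the plateau `P` (the mobile fraction, in %), and the
recovery time constant `τ` (s). Only post-bleach points enter the fit;
pre-bleach frames serve normalization. Each region (inside the bleach spot,
or the surrounding annulus) is normalized to its own pre-bleach mean.
Normalization is *simple*: no second normalization against whole-cell
photofading is applied, because the generator does not model acquisition
bleaching; the per-frame background term in `extract_recovery_trace` is the
hook where such a correction would attach. Reaction-diffusion FRAP models
and two-component fits are out of scope.

The diffusion coefficient is reported only to order of magnitude as
`D ~ L²/τ`, `L` being the bleached-spot diameter — a scaling estimate, not a
model fit.

Fitting uses Levenberg–Marquardt least squares initialized at
`i0 = first post-bleach value`, `P = mean of the last three points`,
`τ = time to half of (P − i0)`. A trace whose plateau estimate does not
exceed `i0` (flat, or monotonically decreasing) is unidentifiable and raises
a fit error rather than returning a number.

### Fusion relaxation and size scaling

When two liquid droplets coalesce, surface tension drives the merged shape
back to a sphere. The projected aspect ratio of the merged region decays as

    AR(t) = 1 + (ar0 − 1) e^(−t/τ_f),

and for liquids `τ_f` grows linearly with droplet size; the slope `K` (s/µm)
of `τ_f` against diameter is the inverse capillary velocity (viscosity over
surface tension). Design choices:

* AR is measured as major/minor axis from second central moments of the
  half-max region — a parameter-free shape metric.
* The *merged* droplet's equivalent diameter `d = √(d₁² + d₂²)` (area
  conservation in projection) is the size variable, not the parent mean.
* The scaling fit is ordinary least squares **with a free intercept**:
  an approximately linear law does not assert a zero intercept, and
  reporting the intercept lets users test it. At least three events spanning
  a ≥ 2-fold diameter range are required; the slope's OLS standard error and
  r² are reported.

### Detection, tracking, events

The segmentation rule is this package's own (disk-like blobs, no learned
model): Laplacian-of-Gaussian seeds over a configurable σ range, each grown
to the half-maximum contour between the local peak and the nuclear
background; the background is the median of the nucleus mask (Otsu threshold
on a heavily smoothed copy, with whole-frame fallback) outside detected
blobs. Detections below `min_area_px` (default 4) or `contrast_min`
(default 1.5× background) are dropped.

Linking is greedy nearest-neighbour, closest pair first, each detection used
once, links beyond `gate_um` (default 1 µm/frame) rejected; ties break by
track id and then detection centroid, making the result invariant to input
order. This is adequate for slow nuclear condensates; global assignment
optimization is deliberately not implemented.

A fusion at frame `t` requires parent track(s) terminating at `t − 1` within
`proximity_um` of a child present at `t` whose area matches the summed
parent areas within `area_tolerance` (default 0.25, absorbing PSF blur at
the neck). Because greedy linking lets the merged blob *continue* one
parent's track, two signatures are recognized: two tracks end and a new one
starts, or one track ends while the continuing track's area jumps by the
ended partner's area. Fission is the exact time mirror. Each track joins at
most one event per frame.

### Colocalization and perturbation response

Colocalization is operationalized from two-channel line scans: Pearson r
between the channels over the condensate span, plus the partner channel's
enrichment (mean over the span / diffuse nuclear baseline). The call is
positive when `r ≥ r_min` (default 0.5) and partner enrichment
`≥ enrichment_min` (default 1.5). A zero-variance channel makes r undefined;
the call is then negative and flagged. The nuclear baseline excludes
nucleoli — regions below the 10th intensity percentile of the smoothed
nucleus, since nucleoli exclude most nucleoplasmic factors — and condensate
pixels (above 1.5× the provisional nuclear median). These thresholds are
explicit operationalizations chosen so that noiseless synthetic positives
and negatives separate cleanly; all are exposed as parameters.

Perturbation experiments (e.g. 1,6-hexanediol dispersal and washout) are
scored per condensate from its contrast series (droplet mean over nuclear
baseline): dispersal time is the first post-treatment crossing below
`contrast_threshold` (default 1.2; values ≤ 1 are rejected since contrast 1
means no condensate), and recovery requires a genuine re-cross — below the
threshold within the post-washout window, then at or above it — within
`window_s` (default 10 s, the timescale on which such condensates disperse
and reform). The recovered fraction is over dispersed tracks only and is
flagged undefined when nothing dispersed.

### Screen statistics

Counts are normalized per sample as `counts / column_sum × 10⁶ + 1`; every
normalized value is ≥ 1 and each column sums to exactly `10⁶ + N_sgRNA`,
which the tests assert to machine precision. Library distributions are
summarized as five-number summaries of log₂ normalized values
(type-7/linear-interpolation quantiles) and compared with a two-sided
Wilcoxon rank-sum test: exact enumeration of all `C(N, n₁)` midrank
assignments when both groups have ≤ 8 values (midranks make tie handling
exact), and the tie-corrected normal approximation otherwise — groups of
9–20 therefore also use the approximation. Multiple distribution comparisons
are Bonferroni-adjusted (appropriate for the small number of pairwise
library comparisons); gene-level q-values use Benjamini–Hochberg.

The gene score — median per-sgRNA log₂ fold change with a permutation null
(size-matched random sgRNA sets drawn from the whole library,
`p = (1 + #null ≥ obs)/(1 + n_perm)`, one-sided for enrichment) — is a
deliberately simple stand-in for dedicated screen rankers such as MAGeCK's
α-RRA, which is not reimplemented. It is sufficient for planted-hit recovery
on synthetic tables and is labelled accordingly.

### Site relocation

Sites carrying an activity mark (e.g. H3K27ac) at two time points are
classified by the pseudocounted ratio `r = (t8 + pc)/(t0 + pc)` into `up`
(`r >` threshold, default 2), `down` (`r < 1/threshold`) and `permanent`.
The pseudocount (default 1) stabilizes near-zero coverage; classification is
invariant under jointly rescaling both intensities and the pseudocount.
"Average intensity" is read as the arithmetic mean over sites; inputs are
assumed depth-normalized upstream. The relocation rate of a factor is the
mean of its intensity over up sites divided by that over down sites: above
1 means the factor follows gained sites.

## Synthetic data: what it emulates, and what it does not

Droplets are uniform disks convolved with a Gaussian point-spread function
(`σ_psf` default 1 px) over a flat background — the simplest model matching
the confocal appearance of nuclear condensates; there is no 3-D optics and
no camera-specific noise calibration (noise is `none`, Gaussian σ, or
Poisson; the defaults are placeholders, not estimates of any particular
microscope). FRAP dynamics are generated in *closed form* — the bleach-ROI
pixels follow exactly the exponential law the fitter estimates — rather than
by explicit diffusion, so parameter recovery can be scored exactly;
an explicit-diffusion mode is a non-goal. Consequently, passing tests
demonstrate correct measurement and fitting machinery, not that real
condensates obey a single exponential.

Fusion series conserve area: the merged ellipse has area `A₁ + A₂` at every
post-contact frame and its aspect ratio follows the relaxation law with
`τ_f = K · d_merged`. Two genuinely tangent uniform disks merge into a
single half-max component once blurred, so pre-contact frames render the
parents pushed apart by a small edge gap (default 3 px) along the contact
axis; the specified geometry is still validated as tangent (overlap is an
error). Perturbation series decay each droplet's amplitude exponentially
after treatment; exactly `round(recover_fraction · n)` droplets, selected by
the seeded RNG, regain amplitude after washout. Default timing
(treatment at frame 10, washout at frame 60, 0.2 s frames, dispersal τ
1.5 s, recovery τ 2 s) places complete dispersal before washout, matching
the regime where condensates disperse within ~10 s of treatment and reform
within ~10 s of washout.

Screen tables draw negative-binomial counts (over-dispersion α default 0.1,
a standard value; at α = 0 counts equal their rounded means) around
log-normal per-sgRNA abundances with mean `depth`; enriched genes have
output means multiplied by `effect_fold`. Site tables draw up-site ratios in
`[fold, 1.5·fold]` (mirrored for down, ±25% band for permanent) so the
planted classes sit strictly beyond the fold threshold, and shift the factor
column per class.

Every simulator is a pure function of its inputs and a single integer seed,
and returns a machine-readable truth record.

## Numerical choices and degenerate inputs

* Curve fits: SciPy Levenberg–Marquardt, `ftol = xtol = 1e-12`, capped
  function evaluations; non-convergence, non-positive τ, or an
  unidentifiable trace raise `FitError` with diagnostics.
* Kymographs and line profiles sample by bilinear interpolation at
  unit-pixel steps (a line of n steps gives n + 1 rows), averaged across
  `width_px` parallel offsets clamped at the frame border.
* Centroids are intensity-weighted above background (sub-pixel).
* Zero-sum count columns, empty site classes, empty nucleus masks, lines
  exiting the frame, overlapping background ROIs, and uncalibrated stacks
  all raise typed errors naming the offending object; they never default
  silently.
* Tracking tie-breaks are documented and deterministic (distance, then
  track id, then centroid).

## Problem sizes used in validation

The test-suite and acceptance-script simulations use 64–128 px frames,
40–120 frame series, 100-replicate Monte-Carlo calibrations, 25–100
repetitions of 30 fusion events, and 1000-gene × 4-sgRNA screens — sizes at
which every estimator's bias is well below its tolerance while a full run
stays interactive on a laptop.

## Known limitations

* Single-exponential FRAP only; no photofading correction, no
  reaction-diffusion interpretation of τ.
* 2-D only; no z-stacks, no 3-D segmentation or colocalization.
* Greedy linking can mis-assign crossing condensates moving faster than the
  gate; the event caller then sees spurious terminations (mitigated by the
  area-conservation check).
* Aspect-ratio measurement is pixel-limited: for merged droplets whose
  minor axis is below ~6 px the relaxation time acquires a discretization
  bias of order 10%; scale comparisons should use well-resolved droplets.
* The permutation gene score is not a replacement for dedicated screen
  rankers on real data.
* Whether real "outside" traces should be normalized to their own
  pre-bleach or to the inside pre-bleach is an open convention; this package
  normalizes each region to itself.
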