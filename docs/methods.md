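# Methods

## Two-compartment tracer model

The simulator and the scoring share one model of tracer kinetics. After a
bolus at time t_inj, the intravascular concentration decays
mono-exponentially,

    B(t) = C0 · exp(−λ (t − t_inj)),

and the parenchymal signal accumulates at a rate proportional to the
instantaneous blood level, dP/dt = k·B(t), giving

    P(t) = (k·C0/λ)(1 − e^{−λ (t − t_inj)}),   (λ > 0)
    P(t) = k·C0·(t − t_inj)                     (λ = 0 limit).

k (per min) is the paracellular permeability rate; λ (per min) the blood
clearance. This is the simplest model consistent with traces that rise
persistently without saturating over a 30-min window, which constrains λ
to be small enough that the window is pre-plateau. Published per-tracer
clearance half-lives are not available for this preparation, so the
defaults (λ = 0.005, 0.02, 0.04 per min for 10 kDa dextran, AF488 and
NaFluo; 0.001 for conjugated albumin) are order-of-magnitude choices and
are exposed in the `GroundTruth` configuration. Leak-rate defaults
(WT: 2·10⁻⁶ / 6·10⁻⁵ / 5·10⁻⁴ per min; knockout: unchanged for the
dextran, 2.7–5.4-fold higher for the small dyes) were set so the
noiseless pipeline lands in the AUC regime reported in vivo (WT NaFluo
≈ 5–6 min, knockout ≈ 28 min); they are calibration anchors, not fitted
quantities.

## Relative change and AUC

The leak score of a tracer is the trapezoidal integral of its relative
parenchymal trace over the 30-min window (AUC, reported in minutes; the
integrand is dimensionless). The relative trace is anchored at the
window's first frame, one minute post-injection.

One convention deserves emphasis. The decoupling correction (below)
operates on background-subtracted traces, but the relative normalization
divides by the *measured* baseline — the corrected window-start value
plus the constant background:

    r(t) = (C(t) − C(t₀)) / (C(t₀) + background).

Dividing by the background-free corrected baseline instead would make the
AUC independent of k (k cancels in P(t)/P(t₀)), destroying the score's
sensitivity to permeability; the measured-baseline convention matches the
fraction-of-first-frame display of in-vivo traces, where autofluorescence
dominates the baseline. The ordering background-subtract → decouple →
relative is the default; `relative_change(trace, baseline_offset=...)`
exposes the denominator explicitly.

## Sequential-tracer decoupling

Three tracers share one detection channel; injections are separated by
the 30-min imaging interval (31 min wall time: 1 min injection-to-first-
frame offset plus the 30-min recording, so windows never overlap). Since
fluorescence is additive, each later trace is corrected by subtracting
the extrapolated exponential fit of every earlier, already-corrected
trace, each fitted on its own window:

* parenchyma: saturating growth a + b(1 − e^{−c(t−t₀)}). Its
  extrapolation is non-decreasing and bounded by a + b, so it represents
  the largest theoretical contribution of a preceding tracer without ever
  inventing signal. Under the two-compartment model this family is exact:
  a time-shifted saturating exponential re-anchors to the same family, so
  on noiseless data the correction is exact to fit precision.
* blood: exponential decay a + b·e^{−c(t−t₀)}, same scheme.

Fit details: nonlinear least squares (scipy), initialization a = first
value, b = last − first, c = 1/window-length, c bounded in [0, 10] per
min. If the fit degenerates, a linear fallback is reported in the c → 0
parameterization (growth with c = 0 evaluates a + b·(t−t₀)/window-length,
i.e. b stores slope × window length; a decay with c = 0 is the constant
a + b). Negative corrected values are retained, never clipped, so
systematic over-correction stays measurable. The correction is asymmetric
by construction: earlier tracers are never corrected by later ones.

The background default is the mean of the pre-injection frame(s) in the
parenchymal ROIs; a constant override is accepted.

`estimate_leak_rate` is a validation oracle, not part of the score: it
fits P(t) ≈ intercept + k·∫B (cumulative trapezoid) by least squares. The
intercept absorbs the accumulation before the window start, which is
non-zero because imaging begins one minute after injection.

## Image front end

Stacks are (T, Z, Y, X); frame i is stamped t₀ + i·Δt (frame start).
Depth is reduced by maximum-intensity projection. Vessels are segmented
on the first projected frame with intravascular tracer by global Otsu
threshold, closing (disk radius 1 px) and removal of components < 20 px;
the threshold is computed per frame, so the mask is invariant to constant
offsets. Parenchymal ROIs are 8×8 px squares (10 by default, pooled into
one trace) placed uniformly at random outside the vessel mask dilated by
3 px, keeping the perivascular halo out; blood ROIs are 4×4 px squares
inside the eroded mask. ROI count/size and pooling are package choices —
the in-vivo protocol states only that ROIs covered vessel-free
parenchyma.

Noiseless stacks are stored as float32 so that extracted traces reproduce
the analytic references exactly; noisy stacks are rounded to 16-bit
unsigned integers as acquired in vivo.

## Vesicle detection and surface density

Puncta accumulate over the session, so each projected frame is reduced to
its difference from the first (pre-uptake) frame, which removes all
static structure. Robust statistics (median, MAD) of the unclipped
difference are computed over the wall band — the vessel boundary dilated
and eroded by 2 px — and detection runs multi-scale Laplacian-of-Gaussian
on the MAD-normalized clipped difference. A detection must lie in the
band, have radius within 0.25–1.5 µm, and exceed median + m·MAD in the
difference image. The defaults are a normalized LoG threshold of 8 and
m = 12: at the simulator's photon counts the commonly quoted m = 3
admits large numbers of shot-noise maxima (the brightest noise peaks
reach ≈ 10 MAD over a session, while true puncta sit above 30); both
parameters are exposed. Because every statistic is scale-normalized,
doubling the detector gain leaves counts unchanged.

Punctum identity across frames is nearest-neighbour linking
(Hungarian assignment) within 1 µm against all previously seen puncta;
unlinked reappearances found new puncta. Detections are attached to the
nearest vessel label within 4 px of the projected label volume. The
statistic per vessel and timepoint is the cumulative distinct-punctum
count per 100 µm² of π·d·L surface; counting is cumulative, so per-vessel
density is non-decreasing, matching the persistent, non-saturating uptake
kinetics. Category aggregates are means over vessels with SEM, and the
per-category appearance rate is recovered as the least-squares slope
through the origin of mean density versus time.

Vessel categories follow a deterministic decision table: d < 6 µm →
capillary; 6–10 µm venous → post-capillary venule; 10–25 µm
through-plane → penetrating arteriole (arterial) or ascending venule
(venous); ≥ 25 µm in-plane at the surface → pial arteriole (< 60 µm) or
pial venule (< 100 µm). The arterial/venous flag must be supplied —
morphology alone cannot decide it — and anything outside the table is
returned as "unclassified", never dropped.

## Synthetic data: what it emulates, and what it does not

The generator renders vessel trees (in-plane vessels as capsules in a
single Z-plane, through-plane vessels as full-depth columns, footprints
disjoint with a 2-px gap), the two-compartment tracer kinetics above,
cumulative Poisson wall puncta (count by time t is Poisson with mean
rate·area/100·t; puncta persist; positions on the wall with a 4-px
minimum separation so rendered spots stay compact), constant
autofluorescence (default 50 a.u.), and Poisson shot noise (gain 1)
followed by Gaussian read noise (σ = 2). Noise uses a piecewise-constant
rate decomposition (vessel / parenchyma / punctum voxels) that is
distributionally identical to voxel-wise Poisson draws but several-fold
faster on large volumes.

It does *not* emulate the optics: no point-spread function, depth
attenuation, motion, bleaching, or hemodynamic fluctuations. Passing
tests therefore demonstrate that the *quantification* is correct and
robust to photon noise — not that segmentation or detection would survive
every artifact of real microscopy.

Morphometry tables (electron-microscopy measures consumed as numbers) are
sampled log-normally per group and measure with configurable mean and CV;
the defaults reproduce the reported endothelial thickness (0.071 µm wild
type, 0.078 µm knockout, 0.070 µm rescue) and cell areas, with CVs
back-computed from the published SEMs at n ≈ 104. The junction-coverage
percentage is resampled while above 100 to respect its (0, 100] support.

Cohort studies draw per-animal leak and vesicle rates as group defaults
times a unit-mean lognormal factor (CV 0.5 for leak, 0.3 for vesicle
rates), emulating the large animal-to-animal spread of in-vivo cohorts;
the paracellular arm uses 7 animals per group and the transcytosis arm 5,
matching the in-vivo group sizes.

## Statistics

Each group is screened with the omnibus (skewness + kurtosis) normality
test at α = 0.05; groups with n < 8 or zero variance default to
non-normal with a logged note. If every group passes, two-group
comparisons use Welch's unpaired two-tailed t-test, otherwise
Mann-Whitney; when both samples are completely tied the result is
reported as U = n₁n₂/2, p = 1 (midrank convention). Morphometry uses
one-way ANOVA on log-values followed by Tukey HSD — the log makes the
test invariant to multiplicative rescaling. Errors are SEM = sd/√n. No
multiple-testing correction is applied across tracers or vessel
categories beyond Tukey, matching the source analysis. Group tests
default to the animal as the unit in cohort studies and the vessel as the
unit in density tables (the bracketed n of the source figures).

## Numerical choices and problem sizes

* AUC integration: trapezoid on the native 1-min grid, endpoints
  interpolated only if a window edge falls between samples.
* Default session grids are desk-scale: paracellular sessions 95 × 8 ×
  256 × 256 at 1.5 µm/px (or 4 × 128 × 128 in repeated studies), vesicle
  sessions 17 × 8 × 384 × 384 at 0.75 µm/px, 7.5-min frames over 120 min.
  The validation studies use 20 seeds (decoupling, leak recovery) or 20
  seeds × 5 sessions (vesicle rate recovery), sizes chosen to keep each
  study in the minutes range on one CPU while providing enough events for
  the stated tolerances.
* Maximum-intensity projection of shot noise biases intensities upward by
  roughly the expected maximum of Z noise draws; because the bias grows
  with intensity, recovered leak rates carry a small positive bias
  (≈ +7% at default noise and Z = 4), well inside the 10% validation
  band. This is a property of MIP-based quantification generally, not of
  the simulator.

## Known limitations

* The correction chain assumes strictly additive fluorescence and
  non-overlapping windows; it has no spectral unmixing.
* Leak scores from different baselines (autofluorescence levels) are not
  directly comparable, since the baseline enters the denominator of the
  relative trace.
* Blob detection is tuned for compact, bright puncta on a locally flat
  difference image; densely clustered puncta closer than the linking
  radius merge into single identities.
* Per-vessel-type paracellular mapping is out of scope (free dye diffuses
  too fast to attribute leak to individual vessels), as are PSF-level
  optical realism and any pharmacokinetic modeling of the rescue
  compound.
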