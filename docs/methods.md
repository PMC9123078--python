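# Methods

## The measurement problem

A polarization-sensitive neuron is recorded while linearly polarized
blue light shines from above and a polarizer rotates 360° clockwise and
counterclockwise at 40°/s, at one of several degrees of polarization
(DoP ladder 0.99, 0.35, 0.1, 0.05, 0.002; the last is effectively
unpolarized light). The analysis asks three questions: does the firing
rate follow the angle of polarization (AoP); how is the response
parameterized (preferred angle, directedness, amplitude, rates at the
preferred and anti-preferred angle); and down to which DoP is AoP
coding reliable for a cell type.

All angles are degrees; time is seconds. The AoP is axial with period
180°, so every circular statistic uses the doubling transform: angles
are doubled mod 360°, ordinary circular statistics are applied, and
mean directions are halved back into [0, 180°). Clockwise rotation is
defined as increasing polarizer angle (recorded in the file header so
data and analysis cannot disagree); analysis angles come from the
commanded polarizer trajectory, not from a monitor photodiode.

## Per-response statistics

**Binning.** Spikes inside a rotation are assigned the polarizer angle
at their spike time, folded mod 180°, into 18 half-open 10° bins with
the first edge at 0°. Counts are pooled over the epoch's rotations;
per-bin exposure is the angular dwell time (equal across bins for
constant-speed full sweeps, 0.5 s per bin per 360° sweep at 40°/s). No
response-latency correction is applied; pooling the two rotation
directions cancels most of the lag-induced angular bias.

**Preferred angle and directedness.** Φ_max and the mean resultant
length r come from the axial vector mean of the per-spike angles. r is
0 for untuned spiking and 1 when all spike angles coincide (mod 180°).

**Significance.** The circular–linear correlation between the 18 bin
counts and the doubled bin centers is tested with the asymptotic
χ²(2 df) statistic n·r_cl². The asymptotic default matches standard
circular-statistics toolboxes; because n = 18 is small, a permutation
test (count shuffling, ≥100 permutations) is available in the
configuration. A measured operating characteristic (see
`polspike.calibration.type_one_error`) confirms the asymptotic test
holds its nominal 5% level in this design. Responses with fewer than
`min_spikes` (default 10) spikes are flagged untestable rather than
tested vacuously.

**Response amplitude.** A = Σ_{i=1..18} |n_i − n̄|, where n̄ is the
rotation's spike count divided by 18. Because n̄ is defined per single
360° rotation, A is computed per rotation and averaged across the
epoch's rotations, while r and the significance test pool rotations.

**Tuning-curve rates.** Rates at Φ_max and Φ_min = Φ_max + 90° are read
off a least-squares fit of the axially bimodal von Mises curve
rate(θ) = b + a·exp(κ·cos 2(θ − μ)) to the binned rates. The
exponential is deliberately un-normalized — the target is a rate curve,
not a density — with a ≥ 0 (mode at μ), b ≥ 0 (non-negative predicted
rate), and κ ∈ [0, 50]. The optimizer multistarts over
μ ∈ {0°, 45°, 90°, 135°} × κ ∈ {0.5, 2}; the best residual sum of
squares wins, ties broken toward the smaller κ. Flat profiles yield
a ≈ 0 with μ flagged unidentifiable; if no start converges the response
falls back to raw bin rates, flagged. As κ → 0 the fitted curve
collapses onto a plain cosine tuning curve (verified in the tests).

**Background activity.** Spike counts in 1 s bins over the 5 s before
lights-on; the median and the 2.5th/97.5th percentiles
(linear-interpolation percentile rule — the convention is stated here
because several exist) summarize it. Epochs with less than 5 s of
stimulus-free lead time are analyzed with a truncated window and
flagged rather than dropped. Rates at Φ_max/Φ_min divided by the
background median give the normalized activity; a zero or missing
median yields a flagged missing value, never an infinity.

**No-stimulus controls.** The epoch's rotation trajectory is shifted
back in time so it ends where the background window begins and is
applied as a sham to that stimulus-free stretch; r, A and mean rate of
the background spikes under the sham trajectory form the null sample
for the threshold analysis. For homogeneous Poisson background the
sham r approaches the analytic null mean √π / (2√n). A configuration
switch (`control_source="lowest_dop"`) instead uses the responses at
the lowest ladder DoP as controls.

## Population statistics

**DoP regressions.** Within a cell type, responses of neurons tested at
≥3 distinct DoPs are pooled and A (or r, or mean rate) is regressed on
DoP by ordinary least squares. If the residuals fail the Lilliefors
normality test at α, the regression is redone on log₁₀(DoP); if those
residuals also fail, the model with the higher R² is kept. The log
transform is applied to the predictor by default (the questions are
phrased as "linear vs logarithmic in DoP"); transforming the response
instead is available for sensitivity analysis. The selection path is
recorded in the result.

**Lilliefors test.** Composite normality is tested by the
Kolmogorov–Smirnov distance from a normal with estimated mean and SD;
since estimation invalidates the standard KS null, the p-value is
Monte-Carlo: the fraction of same-size Gaussian samples (default 2000)
whose statistic exceeds the observed one, add-one corrected. The
statsmodels table-based implementation serves as an independent
cross-check in the tests.

**Threshold for reliable coding.** The no-stimulus control values give
a mean and its two-sided 95% Student-t confidence interval (on the raw
r or A values; no variance-stabilizing transform is applied, which is
conservative for bounded r and is documented as a choice). Walking the
DoP ladder from the highest DoP down, the threshold is the lowest DoP
such that at it and at every higher ladder DoP *every* response exceeds
the upper confidence limit; one outlier at a higher DoP voids all lower
candidates. Controls are per cell type by default, poolable by config.
The procedure is monotone: raising the limit can only raise (or void)
the threshold.

## The synthetic-recording generator

The generator exists so that every stage can be tested against known
ground truth; it emulates the statistical structure the analysis
assumes, not the biophysics. The firing rate of a simulated neuron is

λ(t) = clip( B + s(t)·[ T(d) + M(d)·cos 2(θ(t) − Φ_true) ]
             + on(t) + off(t),  0, ceiling )

with baseline B, in-epoch indicator s(t), commanded polarizer angle
θ(t) (held at its last value between rotations — the physical device
does not jump), axial tuning amplitude M(d) that is either linear
(M = m₀·d) or logarithmic (M = max(0, a₀ + a₁·log₁₀ d)) in the DoP,
tonic term T(d) = τ₀·(1 − d) that is strongest under near-unpolarized
light and vanishes at full polarization (the simplest monotone law
consistent with the observed phenomenology; pluggable), and signed
exponential onset/offset transients modelling phasic responses and
post-stimulus rebounds. Setting `dra_occluded` zeroes every
stimulus-driven term, mimicking occlusion of the dorsal rim area.
Spikes are drawn by thinning a homogeneous Poisson process at the
ceiling rate; sampling is Poisson without refractoriness by default (an
optional dead-time parameter exists, 2 ms when enabled) because the
analysis operates on counts and rates, for which refractoriness is
second-order at these firing rates; 2 ms is the conventional value
when it is enabled.

Cell-type presets encode the qualitative response classes seen under
near-unpolarized light — tonic inhibition with rebound excitation
(most TL2), tonic excitation with rebound inhibition, phasic-onset
inhibition with sustained excitation (most CL1a), offset-only
transients, and no-change cells — with sign constraints fixed per
variant and magnitudes drawn from documented default ranges (baseline
12–25 spikes/s, tuning amplitude ≈ 12–15 spikes/s at full polarization,
tonic gains 2–9 spikes/s, transient amplitudes 3–15 spikes/s with time
constants 0.5–8 s). The amplitude laws are pitched so modulation
effectively vanishes at DoP 0.002. Per-cell magnitudes are package
defaults: the source phenomenology constrains signs and prevalence,
not magnitudes. The default cohort composition (49 neurons across the
six cell types) mirrors a typical intracellular study of this system.

What the generator does **not** emulate: membrane-potential dynamics,
bursting or serial spike-count correlations, slow drifts in
excitability, electrode artifacts, response latency, or optics
(photon flux, diffusor imperfections). Passing tests therefore show
that the estimators are correct and calibrated for Poisson spiking
with the assumed rate structure — not that real recordings meet those
assumptions.

## Determinism and seeding

A master seed is expanded with `numpy.random.SeedSequence` spawn keys
indexed by neuron position, so adding a neuron to a cohort never
perturbs the other neurons' draws. All pipeline stages are pure
functions of (inputs, config, seed); the run manifest records the
config hash and seed, and reruns are bit-identical.

## Validation experiments and problem sizes

`polspike.calibration` fixes the experiment sizes used by the test
suite and the reproduction script: 1000 random inputs for the
brute-force oracles; 2000 unmodulated single-epoch neurons for the
type-I rate; 100 runs for preferred-angle recovery (±10° tolerance,
modulation 15 spikes/s on baseline 20) and for von Mises mode recovery
under Poisson noise; 50 six-neuron cohorts for planted-threshold
recovery; 100 runs per generating law for regression selection;
500 replicates (n = 200) for Lilliefors calibration and power; and
50 mixed cohorts for the directional population trends. These sizes
give binomial standard errors small enough to resolve the bands being
checked while keeping the full validation run around half a minute.

## Known limitations

- The asymptotic χ² p-value is approximate at 18 bins; it measures as
  calibrated in this design, but unusual configurations (fewer bins,
  heavy clipping) should use the permutation option.
- The t-based confidence limit on r treats a bounded statistic as
  Gaussian; with very few controls the limit can exceed 1.
- Thresholds are resolved only to the tested ladder: a true threshold
  between two ladder DoPs is reported as the higher one.
- The sham-control design needs a stimulus-free window at least as long
  as the rotation block plus the background window before each epoch;
  epochs packed tighter lose their controls (logged, not fatal).
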