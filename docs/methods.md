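# Methods

This note documents the models behind each analysis stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices that affect results.

## Observation model and coordinate conventions

Frames are 0-based; positions are in µm with the center of pixel (0, 0)
at (0, 0) µm and x running along columns. The default optics are a
0.1067 µm pixel (16 µm EMCCD pixel at 150× magnification), a Gaussian
PSF of σ = 0.139 µm (≈1.3 px), 500 photons per spot over a background of
10 photons/px, and a frame interval of 32 ms — the acquisition regime of
the reference receptor-tracking assay. Localization tables carry one row
per emitter per frame with a per-axis localization error ε (default
20 nm).

## Synthetic data

`sptlock.synthetic` generates ground truth for every stage:

- **Free diffusion.** Per-axis Gaussian steps of variance 2·D·Δt with
  D = 0.19 µm²/s by default (the unhindered receptor monomer). The box
  boundary is periodic by default so the observable density stays
  constant over thousands of frames; reflecting boundaries are available
  for single-particle studies where position unwrapping is inconvenient.
- **Transient trapping.** A per-particle two-state Markov chain
  (per-frame probabilities `p_arrest`, `p_release`) switches between free
  diffusion and arrest inside a disc of 35 nm diameter centered at the
  entry position. In-disc motion is residual diffusion with
  `d_trap = 0.002 µm²/s`, chosen so the position decorrelates within
  1–2 frames (disc mixing time ≈ R²/(3.4·d_trap) ≈ 45 ms) while single
  steps stay below the disc radius. The boundary is enforced by step
  *rejection* (propose, and stay put if the step leaves the disc): with
  a symmetric proposal this is a Metropolis chain whose stationary
  distribution is exactly uniform on the disc for any step size. Naive
  radial folding of discrete steps was measured to bias the equilibrium
  toward the center by ~13% in the pair MSD, which would propagate
  directly into the domain-size estimate.
- **Oligomers and labeling.** Complex sizes are drawn from a
  configurable distribution; all subunits share one position sequence;
  each subunit is independently labeled with probability `p_label`
  (<0.1 in the reference assay) and assigned channel A with probability
  `color_split`. There is no spectral crosstalk, blinking or bleaching by
  default (the reference acquisition uses photostabilizing buffer and
  short movies; switches exist for robustness studies only).
- **Movie rendering.** Integrated 2D Gaussian spots at the true
  positions, Poisson noise on signal + background, optional Gaussian
  read noise, emitters outside the field silently clipped.
- **FRAP curves.** Ideal normalized recovery
  mf·(1 − exp(−k·t)) on top of a bleach step of configurable depth,
  multiplied by an acquisition-bleach exponential shared with a control
  ROI, plus additive Gaussian noise.

**Motion blur.** By default the simulator records instantaneous
positions, so data generated this way follow MSD = 4Dτ + 4ε² and the
blur-corrected fit returns an *effective* ε with ε_eff² = ε² + D·Δt/3
while D itself is unbiased. With `motion_blur_substeps > 1` the recorded
position is the average over sub-steps spanning the exposure, the
blur-corrected model holds exactly, and both D and ε are recovered
(validated in the test suite with 16 sub-steps).

What the generator does **not** emulate: emitter photophysics (blinking,
bleaching), spectral bleed-through, detection heterogeneity across the
field, sample drift, out-of-focus motion, or interactions between
complexes. Passing tests therefore demonstrate estimator correctness
under the stated statistical model, not robustness to every instrument
artifact.

## Detection and localization

Detection tests, per pixel, a fixed-width Gaussian peak plus constant
background against constant background alone inside a 9×9 evaluation
box. With unknown background and unknown (locally Gaussian) noise level
the generalized likelihood-ratio statistic reduces to the regression
t-statistic of the peak amplitude, which under the null is exactly
Student-t with 9²−2 degrees of freedom — so the threshold for the
nominal per-pixel false-positive rate (default 10⁻⁶) is an analytic
quantile and needs no Monte-Carlo calibration table. Touching candidates
are reduced to local maxima of the statistic (8-connected, row-major tie
break); pixels within half a box of the border are ineligible.
Calibration is verified empirically: on pure-noise frames the measured
rate stays at or below nominal for α ∈ {10⁻⁶, 10⁻³, 10⁻²} (the
local-maximum deduplication makes the test conservative).

Localization fits amplitude, background and the sub-pixel center of an
integrated Gaussian with *fixed* σ by least squares in the box. The
reported precision is a Cramér–Rao-style estimate from the sandwich
covariance of the fit with shot-noise (Poisson) per-pixel variances,
floored at the residual variance; the plain homoscedastic covariance was
measured to under-report the scatter by ~30% at 500 photons. Fits that
do not converge, land at the box edge, or have vanishing amplitude are
dropped and counted. Known limitation: overlapping emitters are not
deflated beyond the local-maximum rule — two emitters closer than about
one PSF width are detected and fitted as one spot.

## Immobile clustering

Immobilization events are found before tracking by a temporal variant of
density-based clustering: a cluster grows frame by frame while the
nearest next-frame localization lies within 120 nm of its running
centroid, tolerating up to 3 missing frames. An event must both span
more than 20 frames (640 ms) *and* contain more than 20 member
localizations. The member-count gate is essential: with the span
criterion alone, gap-bridged chance encounters along free trajectories
produced ~5% spurious events per trajectory (supported by only 9–19
members), whereas with it the false-event rate on free diffusion is
below 1% and the recovered immobile fraction tracks the true
arrested-frame fraction within ±0.05. Whether the original
implementation used a running centroid or a pairwise-distance criterion
is not documented; the running-centroid choice is recorded here, not
asserted as the original. The immobile fraction is computed per frame
(immobile / total localizations) and reported as the time average.

## Tracking and diffusion

Mobile localizations are linked by per-frame-pair optimal assignment
(linear assignment on each connected component of the candidate graph)
minimizing total squared displacement, gated per trajectory at
`gate_factor` (3) times its running RMS step, initialized from a
generous D of 0.5 µm²/s; track ends persist ≤3 frames. An augmented
assignment with explicit gap/birth alternatives was evaluated and
rejected: it converts track fragmentations into identity switches. At
0.5 µm⁻² and D = 0.19 the measured switch rate (~2.1% per linked step)
is at the information-theoretic floor for nearest-assignment linking,
ρ·2π·(4DΔt + 4ε²)/4 ≈ 2.0%.

Per-trajectory MSDs use all gap-free position pairs per lag. Fit weights
follow the standard finite-trajectory variance approximation with the
*model shape* (msd ∝ lag) substituted for the realized values — using
the empirical MSD in its own weight correlates weights with noise and
biased the fitted D 5–7% low in simulations; with model-shape weights
the median-D bias is 1–2%. Fits use the first 5 lags of trajectories
longer than 10 frames; a negative implied ε² is clipped to zero and
flagged, a negative D excludes the trajectory from the ensemble summary
(counted). The reported mobile D is the median over trajectories
(robust to the heavy right tail of short-trajectory estimates); an
ensemble-MSD fit can be assembled from the same primitives if preferred.

## Co-tracking

Channel B is mapped onto channel A by an affine transform fitted by
least squares to matched bead localizations (≥3, non-collinear;
residual RMSE reported and expected at the bead noise level). Per frame,
A and B positions are paired one-to-one within 150 nm by optimal
assignment, with a persistence preference: a combination already paired
in the previous frame has its squared distance scaled by 0.05. Without
this hysteresis, a complex carrying two same-color labels produces two
near-coincident trajectories whose pairing identity flickers (the
per-frame distances are iid noise draws, so the unmodified optimal
assignment switches with probability ~1/2 per frame) and no pair ever
accumulates the required consecutive run. With the factor c the switch
probability is c/(1+c) ≈ 5%. A co-trajectory is a maximal run of ≥10
consecutive co-paired frames of the same pair; any interruption breaks
the run by default (configurable). Dual-labeled fractions are computed
per frame relative to the total localization count of the population and
averaged over time; immobilization events are co-classified when their
centroids fall within the capture radius and their spans overlap by ≥10
frames.

Chance co-localization is controlled by the consecutive-run requirement:
at 0.9 µm⁻² independent channels the measured co-locomoting fraction is
≤ 0.001% (two orders below the 0.05% specificity bound), because a
chance A–B coincidence must survive ~10 frames of relative diffusion
with RMS frame-to-frame relative displacement ≈ 160 nm against a 150 nm
gate.

## Confinement analysis

The confinement index of a 10-frame window is
L = max(0, 2.5117·D₀·t_w/R_w² − 0.2048) with R_w the maximal excursion
from the window's first point and D₀ = 0.19 µm²/s the null mobility;
this is the Simson–Sheetz stay-inside probability in −log₁₀ form. The
exact windowing convention of historical implementations varies (max
displacement vs max pairwise distance, window duration bookkeeping);
any such convention change and any inaccuracy of the closed form are
absorbed by the threshold calibration, which is purely empirical: L* is
the (1 − α) quantile of L over ≥100/α simulated free-motion windows
*including localization noise at the configured ε*, so the null matches
the real observation process. The held-out false-positive rate is
verified ≤ α (default 10⁻³) in the test suite. Absolute L values may
therefore differ from other implementations while the thresholded states
agree.

Profiles are computed on trajectories spanning >100 frames, aligned to
window centers; edges and windows spanning detection gaps are missing.
Frames above L* are arrested; runs shorter than one window (10 frames)
are discarded. Consequences of the windowing: arrests shorter than
about the window length are largely invisible, and detected arrest
boundaries are smeared by ±half a window. The transition-probability
estimates (fully-observed Markov ML on the pooled state sequences,
never counting transitions across trajectory boundaries) inherit this:
when simulated dwells approach the window length, p(arrest) is biased
low and dwell times high. The estimates are exact on the true state
sequences (verified separately), so the bias is a resolution limit of
the 320 ms window, not of the estimator. In the full pipeline the
confinement stage runs on unbiased trajectories (all localizations,
without the immobile pre-filter), since removing immobilization events
first would chop exactly the trajectories whose arrests are under study.

The nanodomain diameter uses the identity E|x₁−x₂|² = R² for positions
uniform in a disc of radius R: the MSD of arrested segments at
decorrelated lags plateaus at R² + 4ε², so
diameter = 2·√(plateau − 4ε²). The plateau is the pooled mean over lags
6–20 within segments; a negative radicand reports diameter 0 with a
flag. Residual lag correlation at lag 6 biases the estimate ~3–5% low
for the default `d_trap`; with ≥10⁴ arrested frames the recovered
diameter is within 10% of the simulated 35 nm.

## FRAP

Normalization is (F(t) − F(0)) / (⟨F_pre⟩ − F(0)) with t = 0 at the
first post-bleach frame; a constant background cancels exactly, and the
normalized curve of an ideal experiment starts at 0 and plateaus at the
mobile fraction. Acquisition bleaching is corrected by dividing by
exp(−k̄·t), with k̄ the mean of single-exponential fits to the
control-ROI series across cells (per-cell correction available);
non-converging fits are dropped and counted, and if all fail no
correction is applied and the result is flagged. The bleach-depth QC
accepts a cell iff at least 40% of the pre-bleach intensity was removed
— the boundary case is treated as acceptable. The 48 s recovery readout
is linearly interpolated (the nearest-frame alternative differs by less
than the frame spacing permits); the plateau is the mean of the final
10% of points. No reaction–diffusion model is fitted: the distorted
bleach geometry of equatorial-plane measurements rules out the standard
closed-form recovery models, so curves are compared directly.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is bit-reproducible
given it; the pipeline summary is byte-identical across repeat runs.
Simulation sizes in the test and calibration suites (e.g. 550
trajectories of 100 frames for diffusion recovery, 2·10⁵ windows for
threshold calibration, 40 pure-noise frames of 512² for detection
calibration, 2000-frame 30×30 µm fields at 0.9 µm⁻² for co-tracking
specificity) were chosen as the smallest sizes at which the Monte-Carlo
error is comfortably below each tolerance being checked.
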