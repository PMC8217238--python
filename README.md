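# sptlock

Single-particle tracking analysis of membrane-receptor immobilization
("lockdown"), built for dual-color single-molecule localization microscopy
of cell-surface receptors such as HER2 crosslinked by multivalent binders.
The package takes image stacks or localization tables and quantifies, per
cell: the immobile fraction, the mobile-fraction diffusion coefficient,
the fraction of co-locomoting (dual-labeled) molecules, transient arrest
in membrane nanodomains, and FRAP recovery — together with a synthetic
two-color data generator so that every analysis stage can be validated
against known ground truth.

## Who this is for

Labs doing TIRF/SMLM single-molecule tracking of membrane proteins who
need a reproducible, scriptable pipeline for:

- spot detection at a controlled false-positive rate (default 10⁻⁶,
  9×9 px evaluation box) and sub-pixel Gaussian localization
  (~7–20 nm precision depending on photon budget);
- spatiotemporal clustering of localizations into transient
  immobilization events (120 nm search radius, >20 frames) and the
  per-frame immobile fraction;
- trajectory linking with up to 3-frame gaps and diffusion estimation by
  weighted MSD fitting;
- dual-color channel registration (affine, bead-calibrated) and
  co-tracking (150 nm capture radius, ≥10 consecutive frames);
- confinement-index segmentation of individual trajectories into
  mobile/arrested states with Monte-Carlo-calibrated thresholds,
  maximum-likelihood transition probabilities and nanodomain-size
  estimation;
- FRAP curve normalization, acquisition-bleach correction and recovery
  metrics.

## The core models

**Diffusion.** Mean squared displacement of a 2D random walk observed
with finite exposure Δt and localization error ε:

    MSD(τ) = 4Dτ − (4/3)DΔt + 4ε²

fitted by weighted least squares over lags τ < 5 frames for trajectories
longer than 10 frames; the mobile-population D is the median over
per-trajectory fits.

**Transient arrest.** A sliding 10-frame window along each trajectory
(>100 frames) is scored with the confinement index
L = max(0, 2.5117·D₀·t_w/R_w² − 0.2048), where R_w is the window's
maximal excursion and D₀ the null (unhindered monomer) diffusion
coefficient, 0.19 µm²/s. The arrest threshold L* is the (1 − α) quantile
of L under simulated free Brownian motion (α = 10⁻³), so free diffusion
is falsely called arrested at a controlled rate. Thresholded state
sequences give the maximum-likelihood per-frame transition probabilities
p(mobile→arrested) and p(arrested→mobile), and the MSD plateau of
arrested segments gives the trapping-domain diameter via
plateau = R² + 4ε² (uniform-in-disc pair-displacement identity).

**Co-tracking.** After affine registration, channel-A and channel-B
positions are paired one-to-one per frame (optimal assignment within a
150 nm radius); a pair that stays matched for ≥10 consecutive frames is a
co-trajectory, evidence of a complex carrying both labels. Fractions are
computed per frame relative to the total localization count and averaged
over time.

**FRAP.** Curves are normalized per cell as
(F(t) − F(0)) / (⟨F_pre⟩ − F(0)) with t = 0 at the first post-bleach
frame, after dividing out a single-exponential acquisition-bleach decay
averaged over control-ROI fits; cells with <40% bleach depth are
excluded.

## Worked example

Simulate a two-color scenario with transient trapping and analyze it end
to end:

```python
from sptlock import synthetic, pipeline

config = pipeline.RunConfig.from_dict({
    "scenario": {
        "n_frames": 400,
        "density": 0.2,              # observable particles per um^2
        "fov": [15.0, 15.0],
        "oligomer_size_dist": {1: 0.7, 2: 0.3},
        "p_label": 0.7,
        "color_split": 0.5,
        "trap": {"p_arrest": 0.02, "p_release": 0.06},
    },
    "seed": 3,
    "threshold_n_sim": 100_000,
})
summary = pipeline.run_pipeline(config)
for k in ("density_um2", "immobile_fraction", "mobility",
          "dual_fraction_mobile", "confined_fraction",
          "p_arrest", "p_release", "domain_diameter_nm"):
    print(k, summary[k])
```

prints (seed 3):

```
density_um2 {'A': 0.10666666666666667, 'B': 0.1288888888888889}
immobile_fraction {'A': 0.16166666666666668, 'B': 0.17586206896551726}
mobility {'median_D_um2_s': 0.17363686831362374, 'iqr_D_um2_s': 0.07481077068737815, 'n_fitted': 77, 'n_negative_D': 0}
dual_fraction_mobile 0.18860662602403952
confined_fraction 0.7741935483870968
p_arrest 0.005846466700559228
p_release 0.04679552390640895
domain_diameter_nm 30.92657469352768
```

Read it as: both channels pass the <1 µm⁻² density gate (per-channel
densities are roughly half the 0.2 µm⁻² observable density because
labels split between colors); ~16–18% of localizations sit in
immobilization events; the mobile-fraction D (0.174 µm²/s) is close to
the simulated 0.19; ~19% of localizations co-locomote (dual-labeled
dimers at 70% labeling); 77% of long trajectories contain at least one
detected arrest; the transition-probability estimates are biased toward
fewer, longer arrests than the simulated 0.02/0.06 because the 10-frame
confinement window cannot resolve the shortest arrests (see
`docs/methods.md`); and the nanodomain diameter comes out at 31 nm vs
the simulated 35 nm — at this small scale a single movie gives a rough
value, while the calibration suite pins it down to ±10% with ≥10⁴
arrested frames.

The same stages are exposed as a CLI:

```sh
sptlock simulate --config scenario.yaml --seed 1 --out run/
sptlock cluster run/localizations_A.csv --out run/events_A.csv
sptlock track run/localizations_A.csv --out run/trajectories_A.csv
sptlock run --config scenario.yaml --seed 1 --out run/
```

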