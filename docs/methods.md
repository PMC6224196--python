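# Methods

This note records the model, the synthetic-data generator, the
quantification conventions and the numerical choices behind `cytograd`,
including where the design was genuinely open and which option was taken.

## 1. The feedback model

### State and geometry

Each recipient cell *i* (1-based from the distal tip; on the 14-cell axis
the two most proximal cells represent the transverse connective) carries
internalized ligand *Cᵢ* (AU), transcription-factor levels
*Pᵢ* (PntP1), *Kᵢ* (Cut), *Yᵢ* (Yan) and a *sty* readout *sᵢ*, all in
[0, 1], a receptor level *Bᵢ* ≥ 0 and a cytoneme emission rate
*nᵢ* ≥ n_floor > 0.  Cells sit at *dᵢ = (i − ½)·cell_diameter* (default
10 µm) from the source.  Cells do not rearrange, divide or move; the
chain is 1-D and updates are synchronous.

### Update rule (one step)

1. **Contacts.** *mᵢ = nᵢ·p(dᵢ)* with *p(d) = e^(−d/ξ)*, ξ = 55 µm.  The
   geometric tail is the minimal monotone model of "an emitted cytoneme
   reaches the source with probability falling in distance"; ectopic
   sources add *strength·e^(−|d − d₀|/range)*.
2. **Availability.** Total expected demand *D = Σ u·Bⱼ·mⱼ* is served with
   availability *a = 1/(1 + D/D_half)* (D_half = 1.2).  This finite
   per-step source output is the one coupling between cells.  It was a
   deliberate design choice: with a non-depleting source every cell's
   steady state is independent of the axis length, and the gradient then
   cannot adapt its steepness to tissue size at all; sharing a bounded
   source output among competing contacts is the simplest mechanism by
   which the same machinery yields steep gradients in short tissues and
   shallow ones in long tissues.  The coupling is kept weak enough that a
   two-cell receptor-null clone in the stalk changes its neighbours'
   steady ligand by <5% (set `demand_half: .inf` for a strictly
   non-depleting source).
3. **Uptake and turnover.** *ΔCᵢ = u·Bᵢ·mᵢ·S·a*, then
   *Cᵢ ← Cᵢ + ΔCᵢ − δ·Cᵢ* (u = 1, S = 13 AU/step, δ = 0.3/step).
   Stochastic mode replaces *mᵢ* with a Poisson draw; *a* is always
   computed from expected demand, so uptake is linear in the draw and the
   stochastic process is mean-equivalent to the deterministic one.
4. **Gene readout.** With Hact(C; θ, h) = Cʰ/(Cʰ + θʰ):
   * s* = Hact(C; θ_sty, 3)
   * P* = Hact(C; θ_P, 3)·(1 − w_KP·K)
   * K* = (1 − Hact(C; θ_K, 1))·(1 − w_PK·P)
   * Y* = (1 − Hact(C; θ_Y, 2))·(1 − w_PY·P)

   Levels relax toward targets at rate 0.2/step.  Activation of sty/pntP1
   is cooperative (h = 3); derepression of cut is deliberately gradual
   (h = 1) and yan intermediate (h = 2), matching the graded proximal
   rise of the repressors and allowing the pntP1 and cut domains to
   overlap at the boundary cell under the half-maximum rule.  Mutual
   inhibition is multiplicative with weights w_KP = 0.2, w_PK = 0.05,
   w_PY = 0.2 — Cut restrains PntP1 more than the reverse, since the
   pntP1-ON cells must still permit the gradual cut rise at the boundary.
5. **Feedback on the machinery.**
   *nᵢ = clamp(1 + 0.2·P − 0.4·K − 0.15·Y, n_floor, 3)* and
   *Bᵢ = clamp(1 + 0.16·P − 0.25·K − 0.1·Y, 0.2, 3)*.  The long-class
   proportion of the emitted length mixture follows the same signs:
   *f_long = clamp(0.1 + 0.6·P − 0.5·K − 0.15·Y, long_floor, 0.9)*, with
   the non-long mass split 0.65/0.35 between short and mid.  Gains on *n*
   and *B* are kept small so the per-cell ligand→gene→machinery→ligand
   loop is a contraction (no bistability, unique steady state); the
   gradient's spatial shape is carried mainly by *p(d)*, while the
   cytoneme *pattern* (the long-class zone) is carried by the
   length-mixture feedback, which does not feed back on uptake.
   The floors encode that cells always retain some short, randomly
   oriented cytonemes.

Clone overrides pin *K*, *P* or *B* in the affected cells and exclude them
from steps 4–5; whole-axis perturbations scale *S*
(`source_overexpression`) or add a second contact kernel
(`ectopic_source`).

### Calibration of the reference configuration

Functional forms and gains above are structural constants.  The four
thresholds were then solved by bisection (`scripts/calibrate_reference.py`)
so that the deterministic 14-cell steady state places the domain
boundaries at sty 1–3, pntP1 1–7, cut 7–14 and yan 11–14 under the
half-maximum ON rule, and the floors n_floor and long_floor were placed at
the geometric midpoint between the raw cell-7 and cell-8 feedback
responses of the 12-cell run, so that cells 8+ clamp to a shared stalk
baseline and the distal zone of above-baseline long cytonemes spans
exactly 7 cells.  The calibration also verifies that the slope statistic
falls strictly with axis length over 6–14 cells.  The frozen result is
`src/cytograd/data/reference.yaml` (θ_sty ≈ 6.61, θ_P ≈ 1.87,
θ_K ≈ 1.64, θ_Y ≈ 0.69, n_floor ≈ 0.90, long_floor ≈ 0.12); analysis code
loads this file and never re-calibrates.

### Numerics

Synchronous updates; convergence when the max-norm step change falls
below 1e-8 (cap 10⁵ steps; the reference run converges in ~140).  A
period-2 cycle (state returning to two steps earlier while still moving)
is detected and flagged.  Mass bookkeeping (Σ C = cumulative uptake −
cumulative decay) closes to 1e-9.  Stochastic runs use one Philox
counter-based generator keyed by the seed and iterate a fixed 400 steps,
reporting the state as a stationary sample.  Non-finite states abort with
a diagnostic.

## 2. The synthetic scene generator

The scene is a 2-D max-projection analogue of a confocal stack: a
constant-curvature tube of radius cell_diameter/2 around an arc-length
midline, pixel size 0.2 µm.  Curvatures bending the tube ≥ 180° are
rejected (distances to the source would lose monotonicity).  The ligand
channel is a diffuse pool (half of the expected intensity
E(d) = background + Cmax·e^(−d/λ)) plus discrete Gaussian puncta
(σ = 0.3 µm) whose *density* carries the gradient: per-cell counts are
Poisson with mean density_scale·E(dᵢ) (default 2 puncta/AU/cell), axial
positions follow E within the cell, and punctum brightness is constant
(60 AU).  The constant-brightness choice keeps band-averaged profiles
proportional to E; brightness statistics of real puncta are unknown free
parameters, recorded in the ground truth, not claims about tissue.  Each
punctum is receptor-bound with probability receptor_binding_prob and
internalized (endosomal) with probability endosome_prob; the surface
(EIF-analogue) channel holds exactly the non-internalized puncta.  Clones
occupy one lateral half of a cell range so the mirrored region across the
midline provides an equal-area control at the same axial position; their
uptake factor scales both pool and punctum density.  Cytonemes are
straight three-vertex polylines from cell centers, lengths drawn from the
short/mid/long mixture, directions von Mises about the source direction
(κ = 4 by default); a trace contacts the source when its reach is at
least the cell's distance, and carries Poisson contact puncta near its
tip (means 5 contacting / 0 non-contacting by default; the two-group
comparison example uses 5 vs 0.5).  Imaging model, in fixed order: PSF
Gaussian blur, Poisson shot noise on expected counts, additive Gaussian
read noise.  One seeded generator drives everything, so identical
configs are bit-identical.

Not modeled (and therefore untested by passing tests): true 3-D volumes
and the two-layer epithelial topology (a "lower layer closer to the
source" is represented as a second scene with shorter distances),
sub-resolution nanopuncta, trafficking kinetics, photorealistic optics,
cytoneme dynamics in time.  Passing recovery tests show the pipeline is
correct on data whose generative model is known; they cannot show the
generator matches real tissue.

## 3. Quantification conventions

* **Profiles.** Band profiles sample every pixel along the (fitted or
  straight) midline and reduce 40 px across the perpendicular.  The
  default reduction is the *mean* across the band — a wide profile line
  averages over its width; the stack itself already stands for the
  Z-maximum projection.  `projection="max"` is available.
* **Trend fit.** v(x) = background + A·e^(−(x−x_max)/λ) by bounded
  nonlinear least squares (log-linear initialization, tolerances 1e-13),
  with x_max pinned at the maximum of a 2-µm-smoothed copy of the profile
  ("maximum average value") and points distal to it excluded.  The slope
  statistic is (Cmax − C½)/(x_half − x_max), computed from the fitted
  curve — equal to A/(2λ·ln 2); fitted rather than raw values make it
  robust to single-pixel spikes.  Non-decaying profiles are returned
  flagged with slope undefined.  Replicate profiles are averaged before
  fitting where several scenes are available, as measured profiles are.
* **Clone ratios.** Total intensity / ROI area (AU/µm²), outside over
  inside; the control ROI defaults to the clone mirrored about the
  midline (equal area within 10%, enforced), minus any self-overlapping
  midline pixels.  Measurement ROIs in the shipped analyses are eroded
  0.8 µm inside the clone border to avoid PSF-scale spillover.
* **Colocalization.** Nearest-centroid distance between punctum sets
  (default 0.5 µm); fraction of set A with a partner in B, monotone in
  the radius.  Recovery tests on ground-truth tables use 0.1 µm, since
  true partners are co-centered and a larger radius counts crowding
  coincidences.
* **Cytonemes.** Length = polyline arc length; orientation = angle of the
  net displacement against the origin-to-source direction (per-segment
  tangents are ignored, matching visual scoring); length bins
  <15 / [15, 30] / >30 µm with the middle bin closed on both ends; rose
  bins 20° and right-closed on (−180°, 180°]; regions tip = cells 1–3,
  mid = 4–7, stalk = >7; a contact punctum is assigned to the nearest
  trace within 1 µm (the visual contact criterion has no stated distance;
  this is a proxy).
* **Statistics.** Welch's two-tailed t-test for two groups; one-way ANOVA
  with Tukey HSD for several.

## 4. Problem sizes in the shipped analyses

Reference simulations use 14 cells (domains) and 12 cells (cytoneme
zone); the scaling experiment runs 6–14 cells.  Recovery analyses use
12-cell scenes of ~780×130 px: decay-length recovery averages 4 replicate
scenes, clone-uptake recovery 50 scenes per uptake factor, wild-type
clone ratios 20 scenes, colocalization 20 scenes, and
stochastic/deterministic agreement 100 seeds.

## 5. Known limitations

The model is a minimal formalization of stated regulatory signs; rate
constants are not fitted to data, so steady-state values are in arbitrary
units and only orderings, boundaries, signs and recovery of configured
parameters are meaningful.  Whether Yan's cytoneme suppression is
independent of Cut is unknown; Yan has its own (smaller) gains and only
the sign is claimed.  Receptor level and cytoneme number enter uptake
multiplicatively; their relative contribution is not quantified by any
data.  The gradient's range is set by δ and ξ, free parameters.  The
strictly-decreasing slope-vs-length behaviour depends on the shared
source pool; with an unlimited source the model predicts
length-independent per-cell states.
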