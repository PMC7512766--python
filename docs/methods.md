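# Methods

This note documents the model, the numerical choices, and the design
decisions behind `oscatt`, in the package's own terms. Nothing here states
an empirical result that the tests or `scripts/acceptance.py` do not
themselves compute.

## Model and assumptions

The package implements an object-based attention model in the oscillatory
correlation tradition: features of one object are represented by
phase-synchronized oscillators, different objects by desynchronized
groups, and attention by a controller that phase-locks onto one group at a
time. Three modelling commitments matter:

1. **Phase, not amplitude.** All readouts use the unwrapped phase
   ψ = unwrap(atan2(y, x)) of each oscillator's (x, y) rotation. Phase
   synchronization (bounded phase difference) is the binding criterion;
   amplitudes stay chaotic and uncorrelated. The printed one-argument
   arctangent form of the phase loses the quadrant and breaks unwrapping,
   so the two-argument form is used throughout.
2. **Fractional order.** Every oscillator carries a Caputo-type derivative
   of order α = 0.9, giving power-law memory. The solver treats α as a
   parameter in (0, 1]; α = 1 recovers the ordinary model.
3. **One-way control.** The central unit reads the network state but never
   feeds back into it, so segmentation results are identical with and
   without attention running.

## Numerical integration

The default solver is the explicit Grünwald–Letnikov scheme with the
short-memory principle. Writing δ_k = s_k − s_0 (constant pre-history, so
the discrete operator matches the Caputo initial-value convention),

    δ_k = h^α F(s_{k−1}) − Σ_{j=1..min(k,L)} c_j δ_{k−j},
    c_0 = 1,  c_j = (1 − (1+α)/j) c_{j−1},

* step h = 0.01: resolves the Rössler cycle (~6 time units) by ~600 steps;
* memory window L = 2000 steps (20 time units): the binomial weights decay
  like j^(−1−α), and the truncation error shrinks monotonically as L grows
  (asserted by test);
* at α = 1 the weights collapse to c_1 = −1, c_j≥2 = 0 and every update is
  algebraically forward Euler. Bit-exactness holds for a single step; over
  a run the δ-offset accumulation reassociates floating-point sums, so
  agreement is to rounding (~1e−13), which the tests assert precisely.
* divergence guard: any |state| > 1e6 or non-finite value aborts with the
  step index (chaotic blow-up detection).

The scheme is first-order accurate; on D^α s = −s it tracks the
Mittag-Leffler solution E_α(−t^α) with error that halves as h halves. An
Adams–Bashforth–Moulton predictor–corrector (full memory, O(n²)) is
provided for cross-checks on scalar systems and small chains; it is two to
three orders of magnitude more accurate at the same step and is used in
tests as an independent route to the same trajectories, never as the
production integrator for grids.

Initial conditions everywhere are i.i.d. uniform [0, 1]³ per oscillator
under a caller-supplied seed; runs are deterministic given the seed.

## Chain coupling and the scan

The 1-D chain couples oscillator j through its x equation with
λ(k_j x_j − Σ neighbours), free boundaries (end oscillators see one
neighbour, k_j = 1). Negative λ is attractive diffusion. The scan
statistic is the cross-oscillator standard deviation of unwrapped phases,
averaged over the second half of the run (the first half is discarded as
transient; the split is standard practice rather than a tuned value). In
this scaled-down setting (N = 10, frequencies evenly spaced over
[0.98, 1.02]) the spread falls monotonically as the attractive coupling
strengthens across the whole scanned grid [−0.15, 0]: stronger coupling
means a more coherent chain, and the minimizer sits at the strong end of
whatever grid is scanned. We found no interior minimum at any tested chain
size (N = 10, 30, 100) or boundary convention.

## Image encoding

Features are 8-bit channels divided by 255, gray = mean(R, G, B), weights
(0.5, 1/6, 1/6, 1/6). Contrast is the weighted mean absolute deviation
from the image-wide feature means; it is a per-pixel quantity in [0, 1]
that depends only on the pixel's values and the global means, so uniform
regions get uniform contrast.

Parameters with units and defaults:

* Δo = 0.04 (dimensionless frequency span): maps contrast onto the
  frequency band [0.98, 1.02], the band pair used by the two-band chain
  experiments; adjacent objects then differ in phase velocity by
  Δo·ΔC per time unit, which sets how long a run must be before groups
  separate cleanly.
* σ = 0.7 (contrast units): width of the Gaussian mapping contrast to the
  coupling strengths. This is deliberately larger than the contrast spread
  of a typical scene: with small σ (e.g. 0.2) the binding coupling
  λ⁺ = λ⁺max·exp(−(1−C)²/2σ²) is numerically zero for any realistic
  contrast (C ≤ 0.75 gives λ⁺ ≤ 2·10⁻³·λ⁺max), no within-object binding
  occurs, and the model cannot segment. σ is a per-image parameter by
  design; 0.7 keeps λ⁺ in [0.4, 0.95]·λ⁺max across the preset contrast
  range.
* θ = 0.1 (feature-distance units): similarity threshold splitting the
  8-neighbour links into binding (similar) and separation (dissimilar)
  sets. Scene presets have inter-region feature distances well above 0.1
  and zero within-region distance, so the split is unambiguous.
* λ⁺max = 0.05, λ⁻max = 0.02: maximum binding and separation strengths.
* Gaussian blur (3×3, sd 1 px) is available for natural images and off by
  default; synthetic scenes are noise-free and hard-edged.

**Sign of the separation term.** The separation links enter the x equation
as −λ⁻·Σ_neg(x_pq − x_jk). With the attractive-diffusion convention fixed
by the chain model (a positive multiplier of Σ(x_nbr − x_self)
synchronizes), a positive multiplier on the dissimilar links would also
weakly bind across object boundaries, which contradicts the term's role;
the minus sign makes dissimilar neighbours repel, which is what
"separation" requires and what the two-region experiments show as
unbounded between-group phase drift.

## Segmentation readout

At a late readout time (default: end of run) the unwrapped phase profile
is clustered in 1-D: sort pixel phases, cut at gaps larger than a
threshold (default 0.3 rad), absorb clusters smaller than 0.5% of the
pixels into the phase-adjacent cluster, and call the cluster owning the
most border-frame pixels "background" (label 0). Two robustness devices
matter in practice:

* **Spatial median (3×3) before the cut.** Object-corner oscillators have
  three same-group neighbours and five background neighbours; the
  separation links drag them off their group's phase, and on scenes with
  many small objects these stragglers can bridge the gap between adjacent
  phase clusters, defeating any gap threshold. The stragglers are isolated
  in image space even when they are not isolated in phase, so a small
  spatial median on the phase map removes them without touching the
  dynamics. The cost is that object corners may be reassigned to the
  background.
* **Minimum cluster size.** Absorbs any remaining stray micro-clusters.

The readout time trades run length against group separation: adjacent
groups separate at ≈ Δo·ΔC radians per time unit, so the desk-scale
presets use 130 time units (three objects, contrast gaps ≈ 0.2) and 200
time units (five objects, gaps ≈ 0.1). Both are package choices recorded
here; the schedule arithmetic is independent of them.

Segment entropy is the Shannon entropy (base 2, 256 gray bins) of the
image inside each segment, averaged over object labels; it measures
segment homogeneity (0 bits for a perfectly uniform segment).

## Control layer

The hybrid system of a group is the componentwise mean of member states;
because the mean is linear, its drift is exactly the mean of member
derivatives, and its phase velocity matches the group's. The control law
u = Ω − F_r(s_r) − K e is the exact-cancellation active-control
construction adapted to fractional order: the closed-loop error obeys
D^α e = −K e *in the discrete arithmetic as well*, because the central
unit is integrated with the same GL scheme that produced the recorded
network trajectory, so the error contracts like E_α(−K t^α) up to solver
tolerance. K = 1 per component; any positive diagonal gain is stable for
all α in (0, 1] since |arg(−K)| = π > απ/2.

Scheduling: one epoch per group, most salient first, onset_k =
t₁ + k·(F_t + 0.01) with t₁ = 20 and F_t = 10 by default; the controller
is off during the 0.01 gaps and after the last epoch. Salience is the mean
member phase velocity over a warm-up window (default (2, t₁); the ordering
is insensitive to the window on the presets because group-mean velocities
average out chaotic fluctuations). An epoch counts as a transition when
|ψ_central − ψ_hybrid| stays below π over the final half of the epoch —
phase synchronization is bounded phase difference, and π is the loosest
bound that still separates locked from drifting pairs, whose difference
grows without bound.

## Synthetic scenes

The generator renders K non-overlapping uniform rectangles/ellipses on a
uniform background with ground-truth labels. It emulates the structure of
the study's artificial scenes — uniform objects, uniform background, desk
scale — not their exact pixels, which are unavailable. Preset colours were
calibrated once against the encoder so that object contrasts come out
strictly ordered and roughly evenly spaced (three-object scene ≈
0.11/0.31/0.53/0.74; five-object ≈ 0.10/0.21/0.32/0.51/0.66/0.75), giving
every scene an unambiguous salience order with yellow the most salient.
Optional additive Gaussian pixel noise is available and off by default.

What passing tests on these scenes do **not** show: performance on natural
images (texture, gradients, soft edges reduce contrast separation and blur
the link split — the paper-style qualitative behaviour is expected but
segmentation accuracy will degrade), robustness of the 1-D phase cut when
object contrasts are nearly equal (two objects with equal contrast are
*designed* to merge: they share a frequency), or any claim about biology.

## Known limitations

* The gap-cut segmentation needs the run to be long enough for the
  smallest contrast gap; it has no mechanism to split groups with equal
  contrast (by construction they synchronize).
* Full-resolution state recording for the control layer is sized for
  desk-scale grids (hundreds of MB at 42×30 over 200 time units); for
  large images run attention on a re-simulation instead.
* The GL scheme is first-order; quantitative trajectories (not phase
  structure) shift under h refinement, which is why all study-level
  checks are phase-based.
* No inhibition-of-return or competition mechanism: the schedule is a
  fixed most-salient-first scan.
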