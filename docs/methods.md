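# Methods

This note documents the models implemented in `rhombosim`, the calibrated
default parameters and why they have the values they do, the numerical
choices, and the known limitations.  All lengths are in characteristic cell
diameters, times in hours (the clock reads hours post fertilization, hpf;
runs span 10.7–12.7 hpf), and concentrations are dimensionless on the
calibrated scale described below.

## Cell mechanics (sub-cellular element scheme)

Each cell is a cluster of `n_e` point elements.  Element pairs inside one
cell interact through a Morse potential
U(r) = u₀ [e^{−2(r−r_eq)/a} − 2 e^{−(r−r_eq)/a}]; element pairs of two
like-type cells through a second Morse potential; unlike-type pairs through
a purely repulsive exponential U(r) = A e^{−r/ρ}.  All inter-cellular
interactions vanish beyond a contact cutoff (2 cell diameters by default),
with the force tapered linearly to zero over the cutoff's last 5% so it is
continuous.  Dynamics are overdamped: element velocity = mobility × summed
pair force, integrated by explicit Euler with the stability bound
dt ≤ 0.2/(drag · max stiffness), where the stiffness is estimated from the
Morse curvature 2u₀/a² (violating the bound raises before any state
change).  Domain walls reflect.  Optional element-level Gaussian jitter
(`element_noise`, default 0.2) models the random movements of cells; it is
small enough not to disturb sorted configurations but frees cells that
would otherwise jam against the domain walls.

**Elements per cell.**  The default is `n_e = 4`.  The calibration
criterion for the intra-cell forces is that an isolated cell initialized
with randomly scattered elements rounds up, asphericity
var(rᵢ)/mean(rᵢ)² < 0.05.  Under all-pairs Morse coupling, clusters of
5–12 elements robustly relax into centered-polygon or multi-shell minima
whose radial variance is far above that bar (asphericity 1/(n−1) for a
centered polygon); four elements relax to a regular square (asphericity
exactly 0) from every random start we tested.  Four-element cells remain
deformable parallelograms and make pair interactions ~9× cheaper than
12-element cells.

**Calibrated force magnitudes.**  Mild sorting: intra (u₀=1.0, r_eq=0.5,
a=0.8), like-type adhesion (u₀=0.3, r_eq=1.0, a=0.4), unlike-type repulsion
(A=0.5, ρ=0.5), drag 1.  "Strong" sorting doubles the adhesion depth at
unchanged repulsion.  These were fixed so that manual checkerboard bands of
width 2 nearly always sort out within the 2 h window while width-4 bands
nearly always fail — the narrow-band-only effectiveness of contact-limited
sorting that motivates the combined model.  Adhesion depths much above ~0.6
at this cell stiffness make the tissue collapse into multi-layer clumps,
which brackets the usable range.

**Long-range variant.**  "Interaction range extended to about three cell
diameters" is implemented as cutoff 3.0 with the adhesion decay length
tripled (a=1.2) and deepened to 0.6, repulsion lightened to A=0.35, plus
element jitter 0.25.  Extending only the truncation radius does nothing —
the mild adhesion tail is numerically zero beyond ~2.2 diameters — so the
variant deepens and stretches the attractive branch, mimicking
chemoattraction toward like cells.  Its parameters were calibrated against
the variant's reported outcome counts (nearly all width-3 bands and most
width-4 bands fully sorted).

## Morphogen field

The extracellular field M_out evolves by explicit FTCS on a dx=0.5 lattice
with mirror (no-flux) boundaries: diffusion (D=10 diam²/h), first-order
removal (1+β)k_M with β=1, k_M=5/h, re-release k_M·M_in from each cell, a
deterministic exponential source V_M(x)=V_max e^{−(x_max−x)/λ} maximal at
the posterior end, and additive lattice white noise η_out√dt N(0,1)/dx per
node (η_out=0.25).  Cells exchange with the field through bilinear
(area-weighted) stencils: each cell samples M_out by bilinear interpolation
at its center and deposits k_M·M_in/dx² with the same four-node weights.
An earlier nearest-node exchange was abandoned because, once sorting
compresses cells, several centers share one node and the concentrated
deposits create spurious morphogen hot spots that flip anterior cells.

The deterministic stationary field is computed with the cells coupled in
(the intracellular pools are independent of the A/B states, so this is
exact), and both the initial condition and all gradient landmarks are
anchored on that operating profile; the cell-free profile underestimates it
by ~60% because of re-release.

## Gene circuit

Each cell integrates (Euler–Maruyama, negatives clipped at zero and counted;
a warning fires if clipping exceeds 1% of updates)

    dM_in/dt = k_M (M_out − M_in) − S(M_in) + η_in ξ
    dA/dt = τ⁻¹ [C_A (a + w_A)/(1 + a + χ_B b + w_A) − d_A A] + η_A ξ
    dB/dt = τ⁻¹ [C_B (b + w_B)/(1 + χ_A a + b + w_B) − d_B B] + η_B ξ

with a=(A/K_A)², b=(B/K_B)², w_A=κ_A M_in, w_B=κ_B M_in⁴ (+ an optional
low-M activation branch used only by the three-zone scenario), and the
saturating sink S(M)=V_S M²/(K_S²+M²).  Defaults: C_A=3.30, C_B=2.52,
d_A=d_B=15/h, K_A=K_B=0.10, χ_A=0.6, χ_B=1.3, κ_A=0.9, κ_B=50, V_S=2,
K_S=1, η_in=0.15, η_A=η_B=0.06, τ=1.

This parameterization was arrived at by requiring, in order:

1. **Anterior protection by structure, not by luck.**  B's self-activation
   is subcritical on its own (C_B/(d_B K_B)=1.68 < 2), so below a morphogen
   onset level (M_in ≈ 0.29) no B-dominant attractor exists at all:
   anterior cells that transiently capture the wrong fate revert
   deterministically.  Without this property, rare anterior B excursions
   accumulate and dominate the extremal transition-width metric.
2. **A bistable salt-and-pepper strip.**  Between the B onset and the fold
   at which the A state disappears (M_in ≈ 0.34) both fates are locally
   stable; the noisy fate-capture race during patterning populates the
   strip with both fates.  The asymmetric cross-inhibition (χ_A<1<χ_B)
   separates the onset from the fold; with symmetric antagonism the
   appearance of the B state immediately destroys the A state and no strip
   exists.
3. **Noise-effective switching.**  The concentration scale K sets the
   quasi-potential barrier heights (∝ d·K²).  With the literal
   half-saturation of 1, stable states sit at O(1) and the printed noise
   amplitudes 0.03/0.06/0.09 cannot cross any barrier within the 2 h
   window (measured 2-h flip probabilities were zero at every level below
   the fold).  At K=0.1 the stable states sit at ≈0.2–0.4 and the same
   amplitudes span weak/medium/strong switching near the fold.
4. **Fast commitment.**  d=15/h makes the capture race and the sub-onset
   reversion transients resolve within the burn-in; slower kinetics leave
   uncommitted cells at t₀ whose flickering readouts masquerade as fates.

The steeper morphogen dependence of B (quartic versus linear for A) makes
the B basin deepen posteriorly — the directional bias that converts noise
into anterior-ward motion of the posterior transition edge.  A single
shared exponent cannot produce an A-anterior/B-posterior pattern from one
monotone gradient, because the ratio of the two drives would be constant
in M.

**Gradient anchoring.**  V_max=3.83 and λ=9.33 place, on the cell-coupled
operating profile of the 14×6 domain, the anterior domain edge at
M ≈ 0.55 × onset (headroom against noise excursions) and the fold at
x ≈ 7.2, which centres a ~4–5-diameter transition band in the plasticity
window.  The three-zone preset (20×6) uses a steeper source (λ=5.5,
V_max=7.0) plus B's low-M branch (κ_B,low=0.5, half-point 0.14, Hill 6), so
B is expressed at both low (r3) and high (r5) morphogen with A (r4)
between; its η_in is scaled down to 0.06 with the narrower bands.

**Initial conditions.**  `init_morphogen` starts cells at small random
expression values with M_in pre-equilibrated against the stationary field
(so the capture race happens at each cell's true local level), then
co-evolves field and circuit with noise for a 1.0 h burn-in before t₀.
The burn-in is the package's own choice: it must exceed both the
commitment time and the sub-onset reversion time at the calibrated
kinetics, otherwise t₀ carries transient pseudo-fates.

## Fates, coupling, scheduling

A cell's fate is its dominant gene (exact ties keep the previous fate;
a virgin tie defaults to A).  In Model SP the mechanical like/unlike
classification is replaced by φ = (A−B)/(A+B+ε) passed through a
saturating ramp (full coupling at |φ| ≥ 0.75): committed cells recover the
discrete Model-S interaction strengths even though their losing gene never
decays exactly to zero, while undifferentiated cells couple weakly.
Attraction weight = max(0, φᵢφⱼ), repulsion weight = max(0, −φᵢφⱼ).
Sequential scheduling (plasticity-then-sorting and the reverse) is
expressed as schedule intervals that must tile the run window exactly.

## Metrics

Transition width TW = max(0, posterior edge − anterior edge + 1) with the
anterior edge the minimum center-x over posterior-fate cells and vice
versa; the manual half-half band of width ITW measures exactly ITW and a
straight sorted interface measures 0.  Mislocated cells are those on the
wrong side of the vertical split x* minimising fate/side disagreements
(ties resolved by the median of the minimising splits, and the mislocated
set is read off at that split).  SI is the population standard deviation of
mislocated-cell distances to the transition midline, defined as 0 when at
most one cell is mislocated.  Outcomes: formed (0 mislocated), nearly
formed (1–2), failed (≥3, or a fate missing from its own zone).  The
best-split rule, rather than the domain midline, keeps the metrics
meaningful when the final boundary settles off-centre (it does, biased
anteriorly).  For three-zone runs each boundary's metrics are restricted
to the half-domain on its side of the midpoint between the two
deterministic switch positions.

The basin-depth surrogate reported by the fixed-point analysis is the
minimal fraction of the straight-line displacement toward the competing
stable state from which a deterministic relaxation escapes the basin
(bisection).  It is a basin-radius proxy, not a true quasi-potential; a
time-to-switch under a fixed sub-threshold perturbation is ill-posed for a
deterministic flow, which is why this surrogate was chosen.

## Numerics and determinism

One shared step dt = 0.005 h satisfies the mechanical (≤ 0.064), diffusive
(≤ 0.00625) and kinetic stability bounds at the defaults; violations raise
rather than clamp.  Pair lists are rebuilt every 10 steps with a 0.4
diameter skin; force accumulation is a strictly serial compiled loop, so
results are bit-reproducible and independent of threading.  Exactly
coincident elements are separated by a deterministic hash-seeded 10⁻⁶
perturbation (logged).  Randomness flows from counter-based generators
keyed by (seed, stream); replicate i of an ensemble uses base_seed XOR i,
so ensembles are reproducible regardless of execution order, and paired
S/P/SP runs of a replicate share the identical generated initial state.

## Problem sizes

Default study conditions: 14×6 cells (84 cells, 336 elements) for two-zone
scenarios, 20×6 for three-zone, (6+ITW)×6 for manual bands, 16 replicates
per ensemble, 400 steps per 2 h run.  A full paired three-model comparison
runs in about two minutes on one CPU.

## What the generator does and does not emulate

The synthetic tissue is a fixed-size 2-D monolayer without cell division,
growth, apoptosis, actin-cable boundary tension, Eph/ephrin signalling
detail, chemotaxis toward organizing centres, or additional morphogens.
Cell counts are tens, matching the scale at which contact-limited sorting
is interesting; conclusions do not transfer to tissues of thousands of
cells where bulk differential-adhesion arguments apply.  Passing tests
demonstrate internal consistency of the mechanisms at these scales, not
agreement with any particular embryo.

## Known limitations

* The calibration reproduces the qualitative mechanism comparison
  (combined model strictly best on ensemble transition width, sorting
  worst; sorting effective only on narrow manual bands; long-range
  interactions rescuing wide bands; plasticity ineffective at the
  low-morphogen three-zone boundary) and most headline widths, but the
  absolute Sharpness Index level runs low: the same reversion physics that
  keeps the anterior zone clean also thins the far-flung mislocated cells
  whose spread the SI measures, so ensemble SI values sit at roughly half
  the original report while preserving their meaning as a relative
  measure.  The combined model's final width (~2.5 diameters) likewise
  stalls above the reported ~1.4.
* The weak-noise arm of the expression-noise sweep ends *narrower*, not
  wider, than the medium arm: in this calibration most of the band's
  disorder at t₀ is metastable rather than deep-frozen, so weak noise
  (which also generates fewer fresh strays) resolves it almost as well.
  The strong-noise arm reproduces the reported anterior-zone erosion
  qualitatively (net A→B conversion deepening with noise) but the net A
  count can drift up through reversions on some seed sets.  Both are
  documented calibration gaps, not metric artefacts.
* Ensemble means over 16 stochastic replicates carry standard errors of
  ~0.2–0.4 cell diameters on TW; comparisons near those margins flip
  between seed sets.
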