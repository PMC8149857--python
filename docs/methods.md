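# Methods

## System and model

The package models a two-population bacterial consortium that implements a
single-layer perceptron.  *Senders* carry a P_lux promoter driving an
OHC14-synthase gene together with an mCherry reporter; an OC6 input dose
activates the promoter, so each sender group converts one element of the
input pattern into a dose of the diffusible signal OHC14, in proportion to
its promoter strength.  Promoter strength — realised in the wet lab by P_lux
point mutants of graded activity and by a P_lux repressor variant for a
negative contribution — plays the role of the perceptron weight.
*Receivers* carry a CinR/P_cin circuit that converts the pooled OHC14 into
EYFP; their measured dose-response is the network's activation function σ.

Three abstractions define the forward model:

1. **Weighted sum.** The collective signal of the mixed senders is the dot
   product s = w⃗·x⃗ on the sender-mCherry axis (mCherry is the measured proxy
   for synthase expression).  No dilution correction is applied for the
   1:19 sender:receiver mixing because the activation function was measured
   under the same protocol and therefore absorbs it.  Negative sums are
   clamped to 0 — a signal concentration cannot be negative — and the clamp
   is logged.
2. **Bit-0 policy.** A "0" input bit contributes exactly zero: experimentally
   those senders are switched off through an aTc-controlled double-inversion
   circuit.  An optional `leaky` mode adds the sender basal activity
   β_m·β₀ instead; it is off by default and not used in any shipped result.
3. **Activation.** σ is the activator Hill form evaluated with the registry
   row fitted on the mCherry axis (K_d = 1103 a.u., n = 2.33,
   β_m = 2.16·10⁴, β₀ = 0.0195).  Units are enforced: a receiver must be
   parameterised on the mCherry axis, senders on the inducer (μM) axis.

## Transfer functions and fitting

Activator: f(x) = β_m·h(x) + β_m β₀ with h(x) = (x/K_d)ⁿ/(1+(x/K_d)ⁿ).
Repressor: f(x) = α_m/(1+(x/K_d)ⁿ) + α₀ α_m = α̂_m·(h − α₀ − 1) with the
signed weight α̂_m = −α_m.  h(0) is defined as exactly 0 (no 0ⁿ ambiguity
for fractional n).

Fitting minimises least squares on log₁₀-transformed responses, because
dose-response data span decades and a linear-scale objective would let the
saturated arm dominate.  Initialisation: K_d from the input level nearest
the response midpoint, n = 1, β_m from the maximum response, β₀ from the
min/max ratio; bounds keep all parameters positive with n ∈ (0.1, 10].
Diagnostics: fits with RMS log₁₀ residual above 0.1 are flagged `poor-fit`
(catches wrong model family), and data whose total response range is below
5% are flagged `flat-response` (n unidentifiable).  Fewer than 4 distinct
input levels is an error, not a flag.

The synthetic dose-response generator emulates the characterization assays:
a 3-fold dilution ladder of 8 levels centred on K_d plus a zero dose, with
replicate counts matching the assays (10 for senders, 3 for receivers, 12
for the mCherry-axis activation curve) and optional multiplicative Gaussian
noise.  Noiseless tables refit to machine precision.  Under 5% noise the
low-cooperativity sender rows (n ≈ 0.35–0.43) do **not** recover K_d tightly:
at n = 0.35 the Hill transition spans more than five decades of inducer
while any realistic assay covers about three, so K_d, β_m and β₀ are jointly
weakly identified.  Monte Carlo over 100 noise draws puts the median
max-parameter error for the shallowest row near 19%.  This is a property of
the measurement design, not of the optimizer, and the tests report it
honestly rather than widening the band.

## Pattern sets

Categories "z", "v", "n" on N×N grids (N ∈ {3,5,7,9}); per category one
clean pattern plus N² single-bit flips, ordered category-major with the
clean pattern first, giving (1+N²)×3 patterns per set.  Clean bitmaps are
configurable; the defaults are glyph stand-ins constrained to (i) the fixed
zero-bit counts 3/9, 16/25, 36/49, 64/81, (ii) "v" and "n" being the
left-right and up-down reflections of "z", and (iii) minimal pairwise
one-bit overlap between the three categories.  Constraint (iii) matters:
with 6 ones in 9 cells any two categories must share at least 3 ones, and a
first draft sharing 5 of 6 made the 3×3 task provably unsolvable (full
enumeration of the 5⁹ discrete weight space showed the best attainable
margin was negative).  The shipped 3×3 bitmap attains the combinatorial
floor (overlaps 4, 4, 3); the N≥5 bitmaps use staggered top/bottom bars and
a shifted diagonal stroke for the same purpose.

Graded ("non-binary") sets multiply every pattern in a set elementwise by a
single random vector u ~ Uniform(0.5, 1), shared across all patterns of that
grid size and recorded in provenance with its seed; zero bits stay zero.
Graded entries scale the calibrated weight linearly rather than
re-evaluating the sender Hill curve at a scaled dose — consistent with how
the graded inputs are constructed from the binary ones.

The 4-bit module enumerates all 16 binary patterns and partitions them by
dot product against lower/upper decision thresholds; membership is always
derived from the thresholds, never hard-coded.

## Weight learning

Loss: L(w) = ½ Σⱼ ((σ(Pⱼ·w) − tⱼ)/β_m)², with targets t given as High/Low
EYFP levels (defaults: H = σ(3K_d) ≈ 20 471, L = σ(0) = 421.2, configurable).
The gradient is analytic through σ (zero on the clamped branch s ≤ 0), with
a central-finite-difference mode as a cross-check.

Continuous stage: seeded uniform initialisation in the positive palette
range; update w ← w − η·K_d²·∇L.  The K_d² factor (receiver dissociation
constant on the weighted-sum axis) makes η dimensionless — the normalised
gradient has units of 1/weight — so the default η = 0.1 moves weights by a
sensible fraction of the axis scale.  A halve-on-overshoot schedule accepts
only non-increasing steps (the recorded trajectory is monotone), regrows η
by 1.2× per accepted step up to its initial value, and stops on loss
tolerance (10⁻⁴), a zero gradient, a 250-iteration plateau, step-size
exhaustion, or max_iter = 10⁴.

Discrete stage: weights are constrained to a level palette — by default the
calibrated sender mCherry levels at the 33.3 μM induction dose
{450, 900, 3500}, plus 0 (absent/suppressed sender) and −735 (the repressor
α̂_m).  Two cadences are supported: project-after-convergence (default)
and project-every-step.  Projection maps each weight to the nearest level,
equidistant ties to the smaller magnitude.  The projected solution is then
refined by **direct search**: exhaustive evaluation of all palette
combinations within ±radius index steps per coordinate (never increasing
the loss; with a radius spanning the palette on small problems this equals
global enumeration).  The exhaustive neighbourhood grows as (2r+1)^d, so a
budget guard (3·10⁵ combinations) refuses oversized requests and training
falls back to iterated greedy coordinate sweeps over the full palette,
which are also monotone.  Because the loss surface has flat regions (σ
saturation, the clamp), training runs 3 independent restarts by default and
keeps the lowest-loss result; everything is deterministic given the config
seed.

Multiclass training fits one weight vector per category against one-vs-rest
targets (each category's run derives its seed from the base seed and the
category index) and reports per-category margins
min(own-category EYFP) − max(other-category EYFP).

## Problem sizes and runtime

Shipped analyses train 3 categories × {3,5,7,9} grids × {binary, graded}
with max_iter = 10⁴ and 3 restarts; the full acceptance run takes about two
minutes on one core.  Direct search is exhaustive for d = 9 (3⁹ neighbours)
and coordinate-based for d ≥ 25.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the study — parameter values,
pattern censuses, sparseness, discrete weight levels, target shapes — so
passing tests demonstrate internal consistency of the model and algorithm,
parameter recovery under the stated noise, and qualitative reproduction of
the headline phenomena (positive margins at every size, better separation
at 5×5 than 3×3, product degeneracy far below 90).  They do not validate
wet-lab fluorescence magnitudes, growth/media variability, sender cross-talk,
spatial OHC14 transport, or cell-to-cell noise; the weight-noise model is a
plain multiplicative CV, not a mechanistic noise budget.  The exact clean
bitmaps and the reference's learned weight tables are not public in machine-
readable form, so the glyphs and trained weights here are constrained
stand-ins: counts such as "distinct products among the 90 combinations"
depend on them and land near, not at, the reference value (17–21 observed
versus 10 reported, against 90 with no degeneracy).

## Known limitations

- K_d recovery for shallow Hill curves (n < 0.5) is intrinsically loose
  under realistic dose ranges (see fitting section).
- The continuous stage can park in clamp-induced flat regions; restarts and
  the discrete direct search mitigate but do not formally guarantee global
  optimality beyond the small-problem regime where enumeration verifies it.
- No multi-layer networks, no stochastic intracellular kinetics, no
  cross-talk or diffusion modelling.
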