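# Methods

This note documents the models, the parameter choices, the numerical
decisions, and what the synthetic experiments do and do not show.

## Thermal-exchange optimization

### Model

The population metaheuristic treats each candidate solution as a body
temperature relaxing toward a paired environment object according to
Newton's law of cooling. One iteration of the loop:

1. sort the population by cost; re-inject the thermal-memory archive
   (capacity `tm_size`, default ⌈PS/10⌉) in place of an equal number of
   worst members; refresh the archive with the current best;
2. pair rank i of the better half with rank n/2 + i (and vice versa),
   padding an odd population with a copy of the best member;
3. decay each member's environment temperature,
   `T_env = (1 − (α₁ + α₂(1 − t))·δ)·T_partner`, δ ~ U[0,1] per member,
   t = iteration/max-iteration;
4. move every member, `T_new = T_env + (T_old − T_env)·exp(−ζ t)`, with
   cooling factor ζ = cost/worst-cost (0 for an all-optimal
   population);
5. with probability Pr per member, reset one uniformly chosen component
   to `lower_j + δ(upper_j − lower_j)·exp(−ζ t)`;
6. *(advanced variant)* build an exchange vector
   `T_b + γ(T_r1 − T_r2)` from the best member and two distinct random
   donors, binomially cross it into the worst member with rate CG, and
   accept the trial only if its cost improves;
7. *(advanced variant)* resize the population by
   `PS ← round(PS + U(−0.5, 0.5)·PS)`, never below the problem
   dimension; shrinking keeps the lowest-cost members, growth appends
   fresh uniform candidates.

All positions are clamped to the box bounds after every update. The
best-ever candidate is tracked outside the population, so the reported
history is monotone non-increasing by construction. Termination is on
an evaluation budget (`max_fes`) or on reaching `error_floor`.

### Parameter defaults and rationale

| parameter | default | meaning |
|---|---|---|
| α₁, α₂ | 0.3, 0.3 | environment-decay weights; mid-range of the values customary for this family of algorithms |
| γ | 0.5 | exchange difference scale (differential-evolution convention) |
| CG | 0.5 | crossover rate of the exchange vector |
| Pr | 0.3 | per-member component-reset probability |
| tm_size | ⌈PS/10⌉ | elitist archive capacity |
| PS | 10·D | initial population (a fixed override, e.g. 150, is supported for high-dimensional neuroevolution where 10·D would be wasteful) |

The component reset in step 5 carries the same `exp(−ζt)` decay as the
cooling move, so late resets concentrate near the lower bound; setting
`perturbation_decay=False` reproduces the plain uniform reset used by
the original algorithm. The normalized time t uses
`max_iteration = ⌈max_fes / PS⌉`, refreshed when the population is
resized, because termination is on evaluations rather than iterations.

Two deliberate properties of the update are worth noting when reading
benchmark results. First, the environment decay multiplies positions
by a factor below 1, which biases the search toward the origin; on the
unshifted analytic suite several optima sit at the origin, so absolute
errors there flatter any member of this algorithm family. The paired
advanced-vs-plain comparison is unaffected (both variants share the
bias), which is why the harness reports the *relative* outcome. Second,
with the exchange and resize extensions disabled the advanced loop is
exactly — bitwise, under a shared seed — the plain loop; the test suite
checks this.

### Benchmark harness

Eight unshifted analytic functions (sphere, bent cigar, Rastrigin,
Rosenbrock, Ackley, Griewank, Schwefel 1.2, expanded
Griewank–Rosenbrock) on the symmetric box [−100, 100], 20-D by
default. Official shifted/rotated competition instances are not
bundled: they require external data files, and the defaults must be
runnable offline. Trials use an error floor of 1e−8 (final errors below
it are recorded as exactly 0) and default seeds 1..n for
reproducibility. The default sweep uses 10⁵ evaluations and 10 runs per
function — problem sizes chosen so a full sweep is a coffee-break
computation rather than a cluster job; the mean/std rows are recomputed
from the logged per-run finals in the tests.

## Preprocessing

Contrast stretch is `y = (x − min)/(max − min)` routed through a
65 536-entry lookup table on the quantized input axis; the LUT is
clipped so the extremes map exactly to 0 and 1, and the LUT path
deviates from the exact affine map by less than 2⁻¹⁵ per pixel. A
constant image raises a degenerate-input error rather than dividing by
zero.

The Wang–Mendel denoiser is supervised: it needs a (noisy, reference)
pair. Antecedent variables are the center pixel and the 3×3
neighborhood mean (reflected padding at borders), each fuzzified on a
7-set triangular Ruspini partition of [0, 1]; the consequent is the
fuzzified reference value; a candidate rule's degree is the product of
its three memberships, and only the max-degree rule per antecedent pair
survives. Inference is product-strength weighting of the consequent
centers (centroid defuzzification); pixels firing no rule pass through
unchanged. On synthetic cohorts the training pair comes from the
phantom generator (clean/noised copies of one field); for external
images a median-filtered copy serves as the reference. The
center+mean antecedent pair is the smallest design that lets the rule
base distinguish isolated noise (center far from local mean) from
structure, which is what the denoiser needs; richer neighborhoods grow
the rule space quadratically for little gain at these noise levels.

## Segmentation

Thresholds are selected by maximizing the between-class variance
σ_b²(k) = ω₁ω₂(μ₁ − μ₂)² over a 256-bin histogram. Because the argmax
of nearly-tied splits is sensitive to float rounding, the selection is
done in exact integer arithmetic on the (integer) histogram counts —
σ_b²(k) ∝ (S₁N − SC₁)²/(C₁C₂) compared by cross-multiplication — with
ties broken toward the lower threshold. The float σ_b² profile is also
returned for diagnostics; the within + between = total variance
identity holds to 1e−10 on the unit-scaled axis.

Mammograms are grayscale, so the default path thresholds intensity
directly: for R = G = B the chromatic normalizations R̂ and X̂ are
constants (1/√3 and a fixed matrix ratio) and carry no contrast. The
R̂/X̂ route is reserved for genuinely chromatic input, where the two
channel masks are combined by intersection (the conservative choice —
a candidate must be salient in both).

A minimum between-class contrast guard (default 0.35 after contrast
stretching) rejects splits whose class means are too close to mark a
mass. The value sits between the two regimes measured on the
generator's output: splits of pure noise or of the breast-field/
background boundary separate class means by ≈ 0.25 or less after
stretching, while genuine masses at the generator's default contrast
separate by ≈ 0.54. Structureless images therefore yield an empty mask
instead of a noise split.

Morphology: hole filling is conditional dilation of a border-background
marker (4-connected) to a fixed point. Opening and closing use
erosion/dilation pairs with `border_value` conventions chosen so that
closing(m) = ¬opening(¬m) holds exactly for symmetric structuring
elements. The default structuring element is the literal 5×5 identity
matrix (a diagonal line); the conventional all-ones square is available
because a diagonal-line element is an unusual choice that leaves
diagonal speckle untouched.

## Texture features

One level of separable 2-D DWT (Haar by default: orthogonal, exact
round trip to 1e−10, energy-preserving) on the mask's bounding-box
crop. Feature subbands default to LL and HL. Each subband is min-max
rescaled to [0, 1] before quantization to 256 gray levels (floor rule,
top of range inclusive) — subband value ranges depend on the wavelet
normalization, so rescaling makes the co-occurrence statistics
comparable across subbands and invariant to constant intensity shifts.
Co-occurrence matrices are computed at distance 1 with offset
convention (row, col) = (round(sin θ), round(cos θ)) for
θ ∈ {0°, 45°, 90°, 135°}, normalized to sum 1, and the five statistics
are averaged over the four angles (averaging, not concatenation, keeps
the vector length independent of the angle set).

Entropy is −Σ f log₂ f with 0·log 0 ≡ 0; correlation is the
standardized product moment, defined as 0 when either marginal
deviation vanishes. A `verbatim_formulas` switch reproduces the
non-standard variants occasionally printed in the applied literature
(entropy without the f multiplier; correlation as (Σ ij f − μᵢμⱼ)/σᵢσⱼ);
the standard forms are the default because only they are bounded and
dimensionally consistent with tabulated feature ranges.

## Classifier and training

Architecture: the 10-value feature vector is treated as a 1-D signal —
conv(4 filters, kernel 3, stride 1) → ReLU → max-pool(2) → dense(8,
ReLU) → dense(2) → softmax, 170 weights in one flat vector
(flatten/unflatten is a bitwise bijection). This is deliberately
desk-scale: every operator of a convolutional classifier is exercised
while the weight vector stays small enough for gradient-free search.

Training minimizes the per-sample-normalized mean squared error between
softmax outputs and one-hot targets with the advanced optimizer
(bounds [−5, 5], population 150, 2·10⁴ evaluations by default).
Cross-entropy with an optional L2 penalty (ρ/2)·Σw² is implemented as a
diagnostic, not as the search objective. Features are z-scored with
training-set statistics before entering the network — the raw
co-occurrence statistics span five orders of magnitude (contrast in the
thousands, homogeneity below 1), which otherwise ill-conditions a
box-bounded weight search; the scaler is stored in the model file and
applied at evaluation time. Class decisions are argmax of the softmax,
ties toward the benign class; malignant is the positive class for the
metrics. Accuracy, sensitivity and specificity are reported in percent
and raise an explicit undefined-metric error on empty denominators
rather than returning a silent zero.

## Phantom generator

Each phantom is a dark detector background (0.05), an elliptical breast
field (base level 0.15, smooth illumination gradient of amplitude 0.06)
and, optionally, a bright mass with a flat-topped radial profile:
constant contrast (default 0.5) inside a core radius (8–12 px at
128×128, jittered per sample) with a Gaussian shoulder of width 2.5 px.
The ground-truth mask marks pixels whose profile exceeds half the
nominal contrast. The flat top is a deliberate choice: a global
threshold landing anywhere on the shoulder recovers nearly the same
region, so segmentation quality measures the pipeline rather than the
accident of where the threshold crosses a smooth peak. The field/
background step (≈ 0.1) is kept well below the mass contrast so that
the between-class variance criterion selects the mass split.

The benign/malignant signal lives in the internal mass texture —
malignant masses carry short-correlation (scale 1.2 px),
high-amplitude (0.10) Gaussian-filtered noise; benign masses smooth
(scale 3.0 px), low-amplitude (0.03) texture — because the downstream
features are co-occurrence statistics: the generator is separable in
exactly the measured space, which is what a parameter-recovery test
requires. Pixel noise is i.i.d. Gaussian (σ = 0.02 by default). All
randomness is drawn from the per-sample seed; cohorts derive per-sample
seeds from one master seed.

What the phantoms do **not** model: pectoral muscle, film labels and
scanner artifacts, spiculated or ill-defined mass margins, overlapping
fibroglandular texture outside the mass, and calcification clusters.
Passing the synthetic end-to-end tests therefore demonstrates that the
pipeline's stages compose correctly and recover a class signal placed
in texture space — not clinical-grade performance on real mammograms,
which depends on data this package intentionally does not ship.

## Problem sizes in the shipped experiments

Segmentation recovery uses 60 phantoms at 128×128 (a 1024×1024
MIAS-like scale is available behind the size parameter); optimizer
efficacy uses the 10-D sphere at 2·10⁴ evaluations over 20 paired
seeds; the suite sweep uses 10⁵ evaluations and 10 runs per function in
20-D. These sizes were chosen so the entire verification suite runs in
well under an hour on one core while keeping the stochastic
comparisons stable across seeds.

## Known limitations

* The environment-decay origin bias discussed above means absolute
  errors on origin-optimum benchmarks overstate performance; rely on
  paired comparisons.
* The chromatic segmentation route assumes the interesting structure is
  red-dominant (R̂) and bright (X̂); other chromatic signatures need a
  different channel pair.
* The Wang–Mendel denoiser is only as good as its reference image; with
  a median-filtered reference it inherits the median filter's edge
  behavior.
* Co-occurrence statistics at 256 levels on small mass crops produce
  sparse matrices; energy and homogeneity are then small and the
  entropy near its maximum, so between-cohort comparisons should fix
  the crop scale.
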