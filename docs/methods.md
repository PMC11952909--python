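# Methods

This note records the models, numerical choices and known limitations of
spinepinn, in the package's own terms. Nothing here states a result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Phantom geometry

The phantom is a stack of alternating vertebra and disc regions along the
cranio-caudal (z) axis: by default five vertebrae (28 mm high) and four
discs (10 mm), cylindrical cross-section of radius 20 mm — dimensions in
the range of adult lumbar anatomy, chosen once for realism of scale; the
anatomy itself (posterior elements, facets, curved endplates) is
deliberately absent, because the identification method, not the geometry,
is under study here.

The mesh is a structured grid: the square [−1,1]² is mapped to the disk by
the elliptical map (x,y) → (x√(1−y²/2), y√(1−x²/2)), extruded through
z-planes, and each hexahedral cell is split into six tetrahedra by the Kuhn
subdivision (the six axis-order paths from corner to corner), which is
conforming across neighbouring cells. Consequences:

- bone–disc interfaces share nodes exactly — tied contact realized
  structurally, with no constraint equations;
- the meshed solid is a prism over an inscribed polygon whose area has a
  shoelace closed form, so the total volume check is exact to roundoff;
- the grid diagonals break rotational symmetry: under pure axial
  compression the volume-averaged shear components are not machine-zero but
  ~10⁻³–10⁻⁴ of the dominant normal component (mesh-convergent, tested at
  <5×10⁻³).

Endplate annotation is a pure per-triangle predicate: a triangle belongs to
the upper endplate iff its outward normal is within `max_angle_deg`
(default 30°) of +z **and** its centroid's signed axial distance from the
surface's axial centroid falls in a band (default: the outer 15% of the
z-extent). The thresholds are configurable because no canonical values
exist; distance is measured along the stack axis from the axial centroid,
which stays well-defined for multi-region stacks where a global origin
would be ambiguous.

## Finite-element solver

Linear 4-node tetrahedra (constant strain), isotropic elasticity per
region, SI units internally (mesh mm → m on ingest). Dirichlet conditions
are imposed exactly by partitioning; the reduced system is solved with
SuperLU, and a collapsed pivot (ratio ≤ 1e−12) is reported as a rigid-body
-mode error. Verification: the constant-strain patch test is exact to
machine precision; external work ½·F·u equals stored strain energy to
~1e−15; reactions on the constrained and loaded sets balance to ~1e−12.

Two boundary-condition modes: `fixed_bottom` (all translations of the
bottom endplate fixed — the physiological sacrum support, default) and
`uniaxial_free` (axial support plus minimal lateral pins), used for
closed-form verification. Note a physical subtlety the tests encode: a
bonded two-layer bar with nonzero Poisson ratios is genuinely stiffer than
the series-spring formula (the stiff layer confines the nearly
incompressible soft layer), so the 1% closed-form match is asserted in the
ν=0 uniaxial state where the formula is exact, and the ν>0 case is
asserted as monotone convergence toward the series bound under refinement.

Quasi-static stepping of a linear model is exact scaling, so each material
is solved once and the load sweep (and per-step fields) are scalings; a
true re-solve per step exists behind `true_stepping` for future nonlinear
materials, and the one-term incompressible Ogden law
(W = (μₒ/α)(λ₁^α+λ₂^α+λ₃^α−3), uniaxial nominal stress
P = μₒ(λ^{α−1} − λ^{−α/2−1}), consistent shear modulus μ = μₒα/2) is
provided at constitutive level for that path.

### Response features and identifiability

The 16 features are F_ext (axial reaction, positive in compression), the
displacement of the loaded-endplate node nearest the set centroid (its u_z
is the prescribed magnitude, so the applied load level is visible to the
network), and six stress + six strain tensor components aggregated over
elements by volume weighting. The aggregation compartment is a documented
design choice with measurable consequences: with moduli differing by ~4
orders of magnitude, whole-model averages are dominated by the compliant
disc, leaving the bone compartment at ~10⁻³ relative feature sensitivity —
unlearnable in practice. The default `split` aggregation therefore samples
each field where it is informative in a stiff–soft composite: stresses over
the disc, strains over the bone; E_disc is then carried strongly by
F_ext vs. the prescribed displacement, E_bone by the bone strain level,
and the Poisson ratios by lateral components. `whole_model`, `bone` and
`disc` aggregations remain available.

## Training data

Materials are drawn uniformly and independently: E_bone ∈ [10, 25] GPa,
E_disc ∈ [1, 4.1] MPa, ν_bone ∈ [0.1, 0.4], ν_disc ∈ [0.45, 0.48]; k and μ
are derived through the isotropic identities, so the target matrix is
internally consistent by construction. Density deserves a caveat:
quasi-static linear responses are density-independent, so an independently
drawn density would be unlearnable in principle. It is instead generated
through an affine Hounsfield relation ρ = c + d·HU with the latent HU
coupled monotonically to the modulus draw (bone: cortical band 700–2000 HU
with ρ = 47 + 1.122·HU, a standard QCT-style calibration; disc: 30–90 HU
with ρ = 1000 + 0.5·HU, water-like soft tissue). This makes the density
columns a proxy for the modulus information — a modelling convenience that
keeps the 10-output learning task well-posed, reproducible in its ill-posed
variant via `rho_independent=True`.

Default dataset sizes are 29 draws × 14 magnitudes = 406 rows for initial
training and 48 × 14 = 672 rows for the calibration/fine-tuning set; rows
are (material, magnitude) pairs, split 70/15/15 by largest-remainder
rounding with z-scores fitted on the training rows only. Because the 14
magnitudes of one material are exact scalings, the effective sample count
is the number of material draws; held-out rows share materials with
training rows, so split accuracies measure interpolation on the response
manifold while the calibration harness (fresh truths) measures true
generalization — the two are reported separately everywhere.

## Physics-informed network

An MLP (reference architecture [64-32-16]; the sweep covers the 11 layouts
from [16] to [128-64-32]) maps z-scored features to z-scored targets. The
loss is the batch-mean squared error on normalized targets plus
λ₁·mean|k̂ − Ê/(3(1−2ν̂))| + λ₂·mean|μ̂ − Ê/(2(1+ν̂))|, each residual
formed in physical units after de-normalization, divided by the std of its
modulus column (so GPa and MPa penalties live on the data term's scale),
averaged over the bone and disc groups; λ₁ = λ₂ = 0.1 by default.
Predictions of ν at or beyond 0.5 are clamped to 0.5−10⁻⁶ inside the
penalty with the event counted, not raised.

Optimization is full-batch Adam (lr 10⁻³) for ≤2000 epochs by default with
early stopping on validation loss; everything — forward, backward
(including the chain through de-normalization and the clamp), Adam — is
numpy, deterministic given the seed, and the gradient is verified against
finite differences in the test suite. Three numerical choices matter and
were adopted after measuring their absence:

- **cosine learning-rate decay** (floor 1% of lr): the |·| penalties have
  constant-magnitude sign gradients whose oscillation under Adam otherwise
  sets a noise floor;
- **pseudo-Huber smoothing of the penalty gradient** (width 0.01 in scaled
  residual units): the reported loss keeps the exact absolute form, but the
  gradient vanishes smoothly at consistency instead of flipping sign;
- **constraint warm-up** (penalties off for the first 30% of epochs, linear
  ramp over the next 30%; validation always scored at full weights): letting
  the data fit take shape first prevents the constraint force from steering
  early training into poor basins. With these three in place the λ=0.1
  penalties reduce the measured constraint residuals relative to the λ=0
  ablation for every seed tested, train and test splits alike.

The accuracy metric is 100 × mean over samples and outputs of
max(0, 1 − |ŷ−y|/|y|), in physical units — a regression "percent accuracy"
defined here explicitly since percentage accuracies for regression have no
canonical definition. Checkpoints are JSON (weights at full float
precision) and round-trip bit-exactly; normalization statistics are part of
the model and are retained through fine-tuning.

## Hybrid calibration loop

The loop couples the forward simulation f with the learned inverse f⁻¹,
anchored on the observed response y_obs of the system under study (for a
synthetic specimen, the response simulated with the ground-truth
properties). The first iterate is x₀ = f⁻¹(y_obs); each iteration
re-simulates, re-predicts, and corrects by the prediction residual with a
stochastic-approximation gain:

    x_{n+1} = x_n + aₙ [ f⁻¹(y_obs) − f⁻¹(f(x_n)) ],    aₙ = 1/n.

Rationale, each point measured during development:

- a composite iteration that drops y_obs after the first step has the
  network's bias attractor as its fixed point, not the specimen — and for a
  perfect inverse it is the identity map, making every starting point a
  fixed point; the anchored residual form has f⁻¹(f(x)) = f⁻¹(y_obs) as its
  fixed-point condition and error dynamics e_{n+1} = A e_n with
  A = I − J_{f⁻¹∘f}, the damped-error behaviour the hybrid method claims;
- only the four elastic constants (E, ν per tissue) have nonzero forward
  sensitivity in quasi-static linear FEA; k, μ, ρ are therefore re-derived
  from the current prediction each iteration rather than iterated
  (iterating a zero-sensitivity component is a neutral random walk);
- a learned inverse carries interpolation roughness of roughly its
  generalization error, so the 1/n gain damps that noise while leaving the
  fixed point unchanged (gain 1.0 reproduces the undamped variant);
- the network is applied to the responses of all 14 sweep magnitudes (exact
  scalings for the linear solver) and its predictions averaged.

With an exact inverse the loop is a projection — one iteration, zero error,
regardless of initialization. Convergence is declared when the relative
step norm (2-norm on property vectors scaled by the network's per-column
target stds) falls to `tol` = 10⁻³ within `max_iter` = 10; the in-loop
load case defaults to the mid-sweep 1.4 mm magnitude, and predicted ν/E/ρ
are clamped into admissible bounds before each re-simulation (events
counted). The contraction estimate is the geometric mean of the last ≤5
successive error-norm ratios (truth known) or step-size ratios (truth
unknown); early ratios mix all eigenmodes of A, so the tail isolates the
dominant one — on a constructed linear stub with spectral radius 0.5 the
tail estimate lands within 5% of 0.5, where the all-ratio mean does not.
An estimate ≥1 raises the divergence flag. Final reports carry the two
isotropic-identity residuals per tissue as diagnostics (the penalties are
soft; residuals are reported, never enforced).

## Pipeline, sizes and runtimes

The `run_pipeline` bundle chains phantom → datasets → (optional sweep) →
train → fine-tune → calibration over fresh truths, with content-hash stage
caching and all seeds derived from the global seed and logged. Default
problem sizes — 8 mm mesh resolution (≈4.2k tets, ≈3.1k dofs), 406/672-row
datasets, 3000-epoch trainings, 5–9 calibration truths — were chosen so a
full study completes in about a minute on one CPU while keeping the
recovery medians stable; finer meshes change the solver cost, not the
method.

## Limitations

- The phantom is geometrically idealized; passing tests demonstrate the
  identification machinery on clean, noise-free, model-matched data and say
  nothing about segmentation error, image noise, or anatomical variability.
- ν_bone is weakly identifiable from axial compression of a stiff–soft
  stack; its recovery (and hence k_bone consistency) is the noisiest part
  of the output, especially near the sampled range edges.
- Held-out split accuracies overstate generalization (shared materials
  across magnitudes); fresh-truth recovery is the honest figure of merit.
- Density is recoverable only through its imposed coupling to the modulus;
  with `rho_independent=True` it is unidentifiable by design.
- The disc is linear elastic in the inverse pipeline; the Ogden law is
  constitutive-level only. Large deformation, contact with sliding,
  ligaments and failure are out of scope.
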