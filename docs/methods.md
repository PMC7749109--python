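# Methods

## Scope

`lvemu` reproduces, at desk scale, a surrogate-modelling workflow for
left-ventricular (LV) mechanics: ensembles of simulated LV responses are
generated over printed material-parameter ranges, and neural networks are
trained to emulate the simulator.  The original workflow used 3D
finite-element (FE) ventricles (a four-chamber human heart for
pressure/volume, a swine LV for diastolic stress).  Those meshes and the
commercial solver are out of scope here; a reduced-order chamber built on
the same constitutive equations stands in as the data-generating process.
What must carry over is the *statistical structure* of the ensembles —
outputs of the right magnitude, smoothness and parameter sensitivity, with
the exact dataset bookkeeping (80/124 models, 401 time points, 576
elements, 8/7 features) — not anatomical fidelity.

## Constitutive model

Passive myocardium follows the anisotropic hyperelastic law with
isotropic (a, b), fiber (a_f, b_f), sheet (a_s, b_s) and fiber–sheet
coupling (a_fs, b_fs) terms in the invariants I₁, I₄f, I₄s, I₈fs of the
right Cauchy–Green tensor, plus the volumetric penalty
Ψ_vol = (1/D)((J²−1)/2 − ln J), D = 2/K.  Two completions of the printed
energy are conventional; this package uses the nearly-incompressible
(deviatoric-invariant) form, evaluating Ψ_dev on J^{−2/3}-weighted
invariants, for two reasons: it is the form implemented by the major FE
codes for this material, and it is the unique reading under which the
reference configuration is exactly stress-free (the plain-invariant form
leaves a spherical stress a·I at F = I).  The two coincide wherever
J = 1, which the chamber solver enforces exactly.  The Cauchy stress is
the standard push-forward σ = (2/J)·F(∂Ψ/∂C)Fᵀ with analytic
derivatives, verified against central finite differences of the energy
(relative tolerance 1e-5) in the test suite.  The fiber/sheet
exponentials use (I₄ᵢ−1)² as printed, so they engage under compression
as well as tension; a tension-only variant is deliberately not the
default.

Active tension is a time-varying elastance law on the sarcomere scale:
T₀ = T_max·Ca₀²/(Ca₀²+ECa₅₀²)·C_t, with the three-branch cosine
waveform C_t(t) peaking at t₀ and relaxing over t_r = m·l + b, and the
length-dependent calcium sensitivity ECa₅₀ = (Ca₀)_max/√(e^{B(l−l₀)}−1),
l = l_R√(2E_ff+1).  Below the zero-active-stress length (l ≤ l₀) the
sensitivity is undefined and the tension is defined as zero — the
physical meaning of l₀.  Total stress is passive plus T₀ acting along
the deformed fiber direction.

### Parameter units and defaults

The design ranges are used verbatim: active
l₀ ∈ (0.0015, 0.0028) (read in mm, i.e. 1.5–2.8 µm — the metre reading
is off by three orders of magnitude for a sarcomere), t₀ ∈ (0.075, 0.25) s,
and T_max ∈ (0.65, 1.9) as a dimensionless multiplier on a baseline
isometric tension of 135.7 kPa (the conventional Guccione-model value;
the source prints no unit for this range); passive
a ∈ (0.387e−4, 9.881e−3), a_f ∈ (5e−4, 49.901e−3),
a_s ∈ (9.1e−5, 6.986e−3), a_fs ∈ (4.4e−5, 3.952e−3) MPa, taken literally.

Constants the source does not print are package defaults, all
overridable: Ca₀ = (Ca₀)_max = 4.35 µM, B = 4.75 µm⁻¹ (Guccione-model
conventions); l_R = 2.1 µm, at the upper end of measured unloaded human
sarcomere lengths — chosen so the sampled l₀ range maps onto a graded
contractility continuum in the reduced chamber (with the textbook
1.85 µm the chamber never exceeds ~2.2 µm and half the l₀ range
collapses onto one zero-ejection response, which misrepresents the
ensembles being emulated); relaxation constants m = 0.5 s/µm,
b = −0.6 s, giving t_r ≈ 0.45–0.65 s over the operating lengths so that
relaxation completes within the cycle (the classical constants scaled to
these longer sarcomeres give t_r > 1 s and an unclosed loop).  Designs
with l₀ ≳ 2.4 µm still produce weak or absent ejection; that tail is a
genuine consequence of the printed range and is retained.  The passive
exponents (b = 4, b_f = 6, b_s = b_fs = 4) and default stiffnesses are
calibrated once to the soft in-vivo range so that the chamber reaches a
physiological end-diastolic volume (~105 ml at 10 mmHg); D = 0.02 MPa⁻¹
(K = 100 MPa).

## Reduced-order ventricle

Wall mechanics are solved for an exactly incompressible thick-walled
equivalent sphere (reference endocardial radius 25 mm, thickness 6 mm):
with r³ = R³ + r_i³ − R_i³ and the equibiaxial shell state
F = diag(λ⁻², λ, λ), radial equilibrium gives the cavity pressure as the
transmural integral P = ∫ (σ_θθ+σ_φφ−2σ_rr)/r dr, evaluated with
Gauss–Legendre quadrature (8 shells) and a closed-form expression for
the deviatoric stress imbalance (tested against the full tensor path).
Incompressibility is exact (Lagrange pressure fixed by the traction
boundary conditions), so the volumetric penalty never enters the chamber
solve.  Passive inflation root-finds the inner stretch for a given
end-diastolic pressure (Brent, pressure residual ≪ 1e-6 mmHg).  In the
isotropic small-strain limit the endocardial stresses agree with the
Lamé thick-walled-sphere solution within 5% (test suite).

Stress fields are reported at 576 patch centroids (24 apex-to-base rings
× 24 counterclockwise azimuths, fixed traversal order) of a truncated
prolate ellipsoid (elongation 1.6, base cut at half the polar semi-axis).
The spherical solution is mapped onto the ellipsoid with local membrane
curvature factors (meridional and circumferential Laplace ratios,
exactly 1 on a sphere) and rotated into the local fiber–sheet frame: the
fiber lies in-plane at the endocardial helix angle (+60°, −60° at
epicardium, linear through the wall), and the sheet is transmural with a
45° tilt.  The curvature factors and the helix/tilt rotation give the
myofiber, cross-fiber and fiber–sheet shear components smooth spatial
variation of realistic relative magnitude (σ_ff of a few kPa, σ_cc and
σ_fs several-fold smaller at 10 mmHg); on a sphere with zero tilt the
shear vanishes identically, which the Lamé test exploits.

The cardiac cycle integrates cavity volume and arterial pressure on a
fixed 401-point grid over 1.0 s (RK4, 6 substeps per interval).  Valves
are one-way resistances (mitral 0.005, aortic 0.02 mmHg·s/ml) into a
windkessel afterload (compliance 1.8 ml/mmHg, peripheral resistance
1.0 mmHg·s/ml, aortic opening 80 mmHg, venous preload 10 mmHg); the four
phases — filling, isovolumic contraction, ejection, isovolumic
relaxation — emerge from the flow switching rather than a scripted state
machine, which makes isovolumic steps conserve volume to machine
precision.  The sampled right-ventricular triplet perturbs preload,
compliance and peripheral resistance through ±20% gains on its
normalized deviations, so all six active design parameters influence the
trace.  The cycle duration (1.0 s) exceeds t₀ + t_r for every admissible
design; loop closure |V(end)−V(start)|/V(start) is ~1e-4 at defaults.
The simulator has no internal randomness: identical inputs give
bit-identical outputs.

## Datasets and surrogates

Designs are Latin-hypercube samples (scipy's sampler, seeded), one
stratum per model and parameter.  Flat tables carry one row per (model,
time point) with features [l₀ᴸⱽ, t₀ᴸⱽ, T_maxᴸⱽ, l₀ᴿⱽ, t₀ᴿⱽ, T_maxᴿⱽ,
time, co-signal] (8) for pressure/volume — the co-signal being the other
measured trace — and [a, a_f, a_s, a_fs, x, y, z] (7) for stress.
Splits are model-wise (all 401 or 576 rows of a model share one
assignment; the rows of one model are not independent samples), with the
validation count = 10% of the training+validation pool rounded half away
from zero (74→7, 77→8, 104→10), and at least one validation model in
degenerate smoke configurations.  Min–max scaling to [0,1] is fitted on
training rows only and persisted with each surrogate.

Sequence datasets window the target with a 20-step lookback; models
chain in ascending design order (each design is treated as the sequence
continuation of the previous one), so only the global first 20 positions
are dropped; batch sizes are 401 (pressure/volume) and 576 (stress).

Because no deep-learning framework is assumed, both networks are
implemented directly in numpy with manual backpropagation, verified
against central finite differences.  The feed-forward surrogate has 3
hidden layers (20 neurons for pressure/volume, 128 for stress; a
7-hidden-layer stress variant is the config default, covering the
alternative "9 counted layers" depth reading), MAE loss, Adam at
learning rate 0.001, and early stopping by snapshotting the epoch with
minimum validation loss.  Hidden activation is tanh with Glorot
initialization (selected over ReLU during hyperparameter tuning — the
emulated workflow itself reports tuning the activation — and clearly
better on smooth waveforms: held-out pressure MAE 0.8 vs 2.0 mmHg);
ReLU remains available.  Training is mini-batched (16 rows for
pressure/volume, 1024 for stress) with a seeded shuffling stream;
full-batch training cannot reach convergence within the 200-epoch
budget.  The LSTM surrogate runs 32 units over the scaled history
channel, concatenates the final hidden state with the current-step
property features into a linear head, resets carry/hidden state every
window, and snapshots the epoch with minimum *training* loss (its
published selection rule); teacher-forced evaluation is the default, a
closed-loop rollout is provided but labelled as outside the emulated
workflow.

## Error analysis

MAE is computed per test model over its 401 time points or 576
centroids, then averaged across the m test models (MAE_Average), with
the sample standard deviation (m−1 denominator) across models; with a
single model the SD is reported as 0 with a warning.  Evaluation refuses
any test model present in the training manifest.  Reports print next to
the published reference errors (shipped as fixed constants, including
the earlier gradient-boosting baseline; never recomputed).

## Problem sizes for the headline runs

The acceptance script and the corresponding tests run the experiments at
the study's ensemble sizes (80/6 and 124/20, three training seeds) with
the pressure/volume surrogate at its full 200-epoch budget and the
stress surrogate at the 3-hidden-layer depth with a 300-epoch budget —
the package's single-CPU problem size; the 2000-epoch, 7-hidden-layer
configuration remains the module default for users with more compute.
Stress training uses float32 arithmetic (the two dtypes agree to the
reported precision), pressure/volume float64.

## What the synthetic ensembles do and do not show

The generator reproduces the input→output map structure the surrogates
were designed for: smooth pressure/volume waves whose timing and
amplitude respond to all six active parameters, and stress fields whose
level and spatial pattern respond to the four passive stiffnesses and
position.  It does not reproduce FE-mesh discretization error, regional
heterogeneity, genuine right-ventricular mechanics (reduced to
preload/afterload gains), atrial dynamics, or solver noise.  Passing
error bounds here therefore demonstrates that the training pipeline and
architectures can emulate a mechanistically grounded simulator of this
structure at the published accuracy — not that they would reach the same
accuracy on the original FE data.

## Known limitations

* The chamber is spherically symmetric at the mechanics level; the
  ellipsoidal stress mapping is a membrane-theory correction, not a 3D
  equilibrium solution.
* Stresses are reported at the endocardial surface only, at a single
  configurable end-diastolic pressure (default 10 mmHg).
* The eject/no-eject boundary inside the l₀ range makes the
  parameter-to-trace map locally steep; surrogate errors concentrate
  there.
* The LSTM surrogate is evaluated teacher-forced; closed-loop rollouts
  accumulate error and are not part of any reported number.
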