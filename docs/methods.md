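# Methods

## Cell model

The simulated cell is the ten Tusscher–Panfilov (2006) human ventricular
myocyte in its **endocardial** parameterization (the reference
conductances G_Ks = 0.392, G_to = 0.073 nS/pF and the endocardial
kinetics of the slow inactivation gate `s` identify the variant). The
state comprises the membrane potential, 12 Hodgkin–Huxley gates, the
ryanodine-receptor availability variable, and the Na+, K+ and three-pool
Ca2+ concentrations (cytosol, subspace, SR) with instantaneous
buffering. Twelve membrane currents sum to the total ionic current; the
SR fluxes (I_up, I_rel, I_leak, I_xfer) close the calcium cycle.

Currents are expressed per unit membrane capacitance (A/F), so the
membrane equation dV/dt = −(I_ion + I_stim)/C_m is integrated with the
capacitance already normalized out; the whole-cell C_m = 0.185 µF enters
only the concentration balance equations. All ten scalable maximal
conductances default to the endocardial reference values and every other
constant follows the source model.

### Integration

Fixed-step **Rush–Larsen**: gates are updated exponentially against
their voltage-dependent steady state and time constant
(x ← x_inf − (x_inf − x)·e^(−Δt/τ)), potential and concentrations by
forward Euler, Δt = 0.02 ms. This is the standard integrator for this
stiff model family (the Na+ activation gate has τ ≈ 1 µs near the
upstroke). Convergence is tested: refining Δt tenfold moves the
last-beat APD90 by < 0.5 ms. An adaptive **LSODA** route integrating
the identical right-hand side piecewise between stimulus edges is kept
as an integration cross-check; the two agree within 1 mV on the 2-ms
output grid over a full beat. The core is JIT-compiled (numba); one
10-beat simulation takes ~0.2 s on one CPU.

Degenerate inputs: a non-finite state is rejected before evaluation; a
NaN appearing during integration raises an error naming the model time.
The L-type driving term has a removable singularity at V = 15 mV,
handled by an ε-offset.

### Initial conditions and stimulus

Simulations start from the model's published 1-Hz paced resting state.
The *quiescent* limit of this model family drifts unphysiologically
(Na_i falls toward ~4 mM over minutes of unstimulated time); that limit
is used only to verify the near-zero resting current residual, never as
a pacing start.

The stimulus is a rectangular pulse, 1 ms long, 50 ms into each
1,000-ms cycle, 10 beats. The stimulus amplitude is not fixed by the protocol definition; the
only external constraint on it is the reference standard APD of
295 ms. We therefore calibrated the amplitude once against that
constraint: −80 A/F reproduces APD90 = 295.7 ms for the unmodified cell
(−52 A/F, the source model's convention, gives 298.4 ms). The same
setting reproduces the published per-channel scan means within ~1 ms
(G_Ks 312.7 vs 311.78; G_CaL 272.9 vs 272.36; G_pK 293.6 vs 292.94), so
it was frozen as the default; it remains overridable in the protocol
config.

### APD definition

"APD" is implemented as **APD90**: the time from the maximum upstroke
velocity (max dV/dt on the sampled grid, before the peak) to 90%
repolarization of the beat amplitude, where the amplitude is the beat
peak minus the pre-stimulus diastolic potential and the downward
crossing is linearly interpolated. A beat whose peak stays below
−20 mV is reported as a **no-AP sentinel** (NaN), not an exception, so
scans over extreme scales (e.g. G_Na × 0.01) can tabulate
loss-of-excitability conditions; such conditions stay in the classifier
dataset (their difference shape is still informative) but are excluded,
with a reported count, from APD statistics.

## Conductance scan and difference shapes

One conductance at a time is multiplied by every multiple of the grid
step in [0.01, 1.99] excluding 1.0 — 198 scales × 10 channels = 1,980
conditions at full scale. Class labels 0–9 follow the reference-table
row order (GKs=0, GKr=1, GK1=2, GNa=3, GbNa=4, GCaL=5, GbCa=6, Gto=7,
GpCa=8, GpK=9). The classifier input is the raw difference
standard − variant restricted to the **last beat** (500 samples at
2 ms): the last beat is closest to the paced steady state and keeps the
input dimensionality small; a config flag widens the window to all
beats.

APD statistics per channel use a one-sample two-sided t-test of the
channel's variant APDs against the scalar standard APD — there is a
single standard value, so a two-sample test is not defined for this
design.

Scale presets: `full` (step 0.01, 10 beats), `reduced` (step 0.05,
10 beats — 380 variants, the desk-scale configuration used by the
reproduction script), `fixture` (step 0.25, 3 beats — test-suite scale
only, not a scale any result is quoted at).

## Classifier

One hidden layer of 130 ReLU units, 10-way softmax, categorical
cross-entropy, Adam with learning rate 0.001, batch size 32, stratified
80/20 split. The fit is delegated to scikit-learn's MLPClassifier with
the architecture pinned; splitting, seeding, evaluation and the weight
dump are owned here. Inputs are the raw mV differences (they are
already centered near zero outside the perturbation's signature);
z-scoring is available behind a flag but measured slightly worse.

Training runs up to 500 epochs with the optimizer's training-loss
tolerance stop. Early stopping on a validation carve-out is available
but **off by default**: on the reduced grid (304 training samples) the
10% carve-out plus patience-25 stopping cost 3–8 macro-F1 points across
seeds (0.89–0.99 with, 0.97–1.00 without). At fixed seed the whole
pipeline is deterministic; metrics are invariant to sample order
because the seed governs the shuffle.

Ten-fold stratified cross-validation is provided
(`classifier.cross_validate`) and returns per-fold reports plus
mean/SD summaries.

## Evaluation

Per-class rates are the one-vs-rest reductions: recall TP/(TP+FN),
precision TP/(TP+FP), F1 their harmonic mean, specificity TN/(TN+FP),
per-class accuracy (TP+TN)/N. The overall score is the unweighted mean
of the ten per-class F1s (macro-F1). Conventions: a class absent from
the truth has undefined (NaN, "missing") recall and F1 — never silently
0 — and macro-F1 refuses to average over missing classes; a *present*
class with no true positives scores F1 = 0. ROC and precision–recall
curves are one-vs-rest over the class-probability threshold with
trapezoidal AUC.

## Drug validation

Pore block is the standard Hill-type conductance multiplier
b(D) = 1/(1 + (D/IC50)^h); the drug's labeled target conductance is
multiplied by b at concentrations 1, 2, 3, 4, 5, 10, 15, 20 × Cmax.
Identities: b(0) = 1, b(IC50) = 0.5 for any h, b strictly decreasing in
dose. Each drug blocks exactly its labeled channel — ibutilide → G_Ks,
dofetilide → G_Kr, diltiazem → G_CaL. (The ibutilide→I_Ks target assignment is this pipeline's labeling
convention; pharmacology literature predominantly reports I_Kr block
for ibutilide.)

Assay variability is emulated synthetically: per drug, a base table of
30 replicate (IC50, h) rows with lognormal dispersion (σ_ln = 0.3 on
IC50, 0.1 on h) is resampled with replacement to 2,000 bootstrap pairs,
from which 10 are drawn without replacement. The bundled base values
are **synthetic order-of-magnitude stand-ins**, not measured assay
data:

| drug | target | IC50 (nM) | h | Cmax (nM) |
|---|---|---|---|---|
| ibutilide | G_Ks | 1000 | 1.0 | 100 |
| dofetilide | G_Kr | 5 | 0.9 | 2 |
| diltiazem | G_CaL | 760 | 0.7 | 122 |

They are chosen so the 1–20 × Cmax protocol spans mild to strong block
(remaining conductance ~0.97 → 0.33 for ibutilide, ~0.7 → 0.09 for
dofetilide, ~0.78 → 0.31 for diltiazem) while staying inside the
conductance range covered by the training scan — a tolerated drug's
Cmax sits at or below its IC50, and blocks far outside the scanned
range would ask the classifier to extrapolate. Real assay tables
replace the stand-ins via a CSV (`drug, ic50, hill, cmax[, target]`).
Because the parameters are synthetic, published per-drug F1 values are
reproducible only qualitatively; the quantitative checks kept are the
dataset size (240), the block-fraction identities, and high recall of
the drug-target classes.

## What the synthetic data does and does not show

All inputs are simulation-generated: the "data" are deterministic solutions of one cell model
under single-conductance perturbations, plus synthetic drug dispersion.
Passing tests therefore show that the difference-shape → channel mapping
is learnable and robust *within this model world*. They do not show
robustness to measurement noise, beat-to-beat variability, multi-channel
drug action, cell-to-cell parameter variation, or model-form error —
none of which the generator emulates. The mechano-electric feedback of
real myocytes is likewise not modeled.

## Problem sizes used by the shipped checks

The reproduction script and acceptance-level tests run the reduced
preset (step 0.05: 380 ten-beat simulations, ~2 min) rather than the
full step-0.01 grid (1,980 simulations), plus full 198-condition scans
of three single channels for the APD statistics; unit tests use the
fixture preset. These sizes are the package's desk-scale defaults; the
full grid is available through `--preset full` / `--step 0.01` and
behaves identically, only slower.

## Known limitations

- Single-cell, endocardial only; no epi/M-cell variants, no tissue
  coupling, no temperature scaling, no stochastic gating.
- One conductance perturbed at a time; no joint perturbations or
  multi-channel drug profiles, no state-dependent drug binding.
- The 2-ms output grid quantizes the upstroke-time estimate in APD
  measurements to ±1 sample (the repolarization crossing is
  interpolated).
- The drug parameter defaults are synthetic; per-drug performance
  numbers with real assay tables will differ.
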