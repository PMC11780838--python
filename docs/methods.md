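# Methods

## Model

A nonnegative activation matrix E (m muscles × 101 gait-cycle grid points,
heel strike at grid point 0, endpoint duplicated) is modeled as the product
of a module weight matrix W (m × n, columns unit-max) and an activation
pattern matrix C (n × 101), plus residual:

    E = W · C + e,    W, C ≥ 0.

Goodness of fit is the variability accounted for,
VAF = 1 − Σe² / ΣE², a global quantity over all muscles and grid points.
VAF is 1 for a perfect fit, 0 for an all-zero reconstruction, and can be
negative for reconstructions worse than predicting zero.

## Extraction and module-number selection

NMF uses the Lee–Seung multiplicative updates for the squared Frobenius
objective, with a small additive constant (1e-12) in the denominators for
numerical safety.  The objective is nonincreasing across iterations (the
test suite asserts this on the recorded per-iteration history).  Each
factorization is restarted from seeded uniform-random nonnegative
initializations — 20 restarts by default — and the highest-VAF replicate is
kept.  Convergence: relative objective change < 1e-6 or 2000 iterations.
After convergence, W's columns are rescaled to unit maximum with the
inverse scaling applied to C's rows, leaving W·C unchanged; muscle rows
that are identically zero in E are set to exactly zero in W.

The module number for a data set is the **smallest n whose
best-of-replicates VAF strictly exceeds the threshold** (0.95 primary,
0.90 sensitivity), searching n = 1..10 for the full 43-muscle set and
1..8 for the 8-muscle subset.  If the threshold is never reached, n_max is
returned with an explicit flag and a warning.  Because restarts at each n
are independent, the reported VAF curve is monotone in n only up to
restart jitter; with ≥ 10 restarts the non-monotonicity is below 1e-3 in
practice.

Multi-restart NMF has local optima: occasionally two restarts reach
essentially the same VAF with visibly different W (the data constrain W·C
more tightly than W).  The default 20 restarts makes the retained W stable
for the structure comparisons; module-number selection is insensitive to
the restart count much earlier, so study runs may use 10 restarts per
candidate n for the VAF curves.

## Structure comparison and fixed-module reconstruction

Module weight vectors are compared with Pearson's linear correlation
(scale- and offset-invariant, so the unit-max convention does not matter;
constant vectors raise an error rather than propagating NaN).  Module sets
are matched one-to-one by linear-sum assignment maximizing total r; with
unequal counts the pairing covers min(n_ref, n_target) modules and the
leftovers are reported unmatched.  Bilateral (left-vs-right) similarity is
the mean/min/max r over matched pairs.

Fixed-module reconstruction solves min ‖W_ref·C − E‖_F subject to C ≥ 0.
The Frobenius objective decouples over grid points, so each time column is
an independent NNLS problem solved exactly (active-set NNLS); the result is
scored with VAF.  Because NNLS is optimal given W, reconstructing a
condition with its own converged W reproduces its extraction VAF to within
the NMF convergence tolerance.

## Recruitment metrics

* **Peak activation**: the maximum of a pattern (positively homogeneous).
* **Center of activity (CoA)**: the gait cycle is mapped onto the circle —
  grid point k → θ_k = 2πk/(T−1) under the duplicate-endpoint convention —
  and the resultant vector A = Σcos(θ_k)c_k, B = Σsin(θ_k)c_k gives
  CoA = atan2(B, A), wrapped to [0, 2π).  atan2 (not arctan of B/A) is used
  because A may be negative.  The primary reported scale is the cycle
  fraction CoA/2π, with radians alongside.  CoA is undefined for all-zero
  patterns and for (near-)uniform patterns; the duplicated endpoint gives
  an exactly uniform pattern a spurious resultant of relative length 1/T,
  so resultants below 2/T of total activity are treated as undefined.  With
  `duplicate_endpoint=False` (θ_k = 2πk/T) circular-shift equivariance is
  exact, which is the convention the property tests use.
* **DTW distance**: classic dynamic programming with local cost |a_i − b_j|,
  step set {(1,0), (0,1), (1,1)}, both endpoints anchored, no warping
  window, returning the unnormalized total path cost.  DTW is computed on
  the reconstructed patterns against the reference condition's
  reconstructed patterns (not the raw extraction C's), so the reference
  condition's own DTW is exactly zero.  No amplitude normalization is
  applied before DTW — amplitude differences are part of what it measures.

## Synthetic generator

The generator emulates muscle activations of simulated walking over a
3 × 3 × 3 condition grid (speeds 0.8/1.1/1.45 m/s, step-length asymmetry
0/15/30 %, step widths 0.1/0.2/0.3 m), both legs, with the reference
condition 1.1 m/s / symmetric / 0.1 m.  Planted structure:

* **W_true** — canonical walking modules: a stance extensor module
  (glutei, knee extensors, with adductor/abductor and hamstring
  representation), a plantarflexor module, a hip-flexor module, and an
  ankle-dorsiflexor module.  The 8-muscle subset supports only three
  (no hip flexor is among its muscles).  Muscles without a nominal role
  get a small uniform weight (0.05); columns are unit-max.
* **C_true** — Gaussian bumps in circular gait phase, centered at
  0.17 (extensor, wide — through much of stance), 0.47 (plantarflexor,
  late stance), 0.62 (hip flexor, stance-to-swing transition) and 0.97
  (dorsiflexor, late swing wrapping into early stance) cycle fractions,
  with reference peak amplitudes 0.37/0.44/0.26/0.38 activation units —
  magnitudes typical of module recruitment on unit-max modules.
* **Condition modulation** (all gains are config parameters; zeroing them
  makes C condition-invariant): speed scales the plantarflexor and
  dorsiflexor peaks (gain 0.8 per relative speed change) and shifts the
  plantarflexor burst slightly earlier; asymmetry scales the hip-flexor
  peak up (gain 0.6 at 30 %) on both legs and attenuates late-stance
  extensor/plantarflexor activity on the shorter-step side (positive
  asymmetry = larger right steps ⇒ left side); step width adds a
  swing-phase bump to the extensor module (its abductor/adductor
  musculature placing a wide step).
* **Noise** — additive i.i.d. Gaussian, sd 0.02 in activation units,
  truncated at zero; simulated activations are much cleaner than
  experimental EMG, and this noise level preserves recoverable modular
  structure while still exercising the model-selection machinery.
* **Determinism** — every noise draw comes from a stream keyed on
  (seed, condition, leg), so any condition can be regenerated in isolation.

What the generator does **not** emulate: musculoskeletal dynamics,
inter-muscle noise correlations, trial-to-trial variability, electromechanical
delay, or any EMG measurement chain (rectification, filtering, normalization
to maximum voluntary contraction).  Passing recovery tests therefore show the
pipeline is correct and well-conditioned on low-rank-plus-noise gait-like
data; they do not show that real EMG has this structure.  Activations are
emitted on a unit-peak module scale without per-muscle renormalization, and
the pipeline applies no normalization before NMF — an explicit assumption.

## Study pipeline

For every condition and leg: VAF curve and module number at both
thresholds; extraction at the primary-threshold n; optimal matching and
Pearson similarity against the reference condition's modules;
reference-module NNLS reconstruction VAF; per-module peak/CoA/DTW of the
reconstructed patterns against the reference's reconstructed patterns.
Legs are analyzed independently end-to-end; bilateral similarity is a
derived table.  A failed condition is recorded and skipped without
aborting the run (the reference condition must succeed).  All tables and a
JSON run log (seed, config hash, versions, VAF curves) are written as
plain text; re-running with the same config reproduces them exactly.

Problem sizes: the shipped study runs and the acceptance script use 10 NMF
restarts per candidate n for VAF curves and 20 for retained extractions,
over the full 27 × 2 grid (8 × 101 subset matrices; the 43 × 101 full-set
analysis extracts reference modules and reconstructs all conditions).

## Known limitations

* NMF local optima can leave one matched module just below r = 0.9 against
  the planted truth in rare seed/condition combinations even at identical
  VAF — an identifiability property of the factorization, not a bug; more
  restarts reduce the incidence.
* The VAF criterion is global; no per-muscle criterion is applied, so
  poorly explained minor muscles can hide behind a high global VAF.
* DTW here is the scalar, full-band, unnormalized variant; distances grow
  with series length and amplitude scale.
* The generator's modulation gains encode qualitative directions
  (orderings), not fitted magnitudes; only orderings should be compared
  against real data.
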