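# motormod

Motor-module (muscle-synergy) analysis of gait-cycle muscle activations.

## The scientific problem

Walking is controlled through a small number of **motor modules**: groups of
co-activated muscles (a weight vector **w**) recruited together by a shared
activation pattern (a time course **c**) over the gait cycle.  A central
question in motor control and rehabilitation is whether the changes in
module number and structure observed in pathological gait (stroke,
Parkinson's disease, cerebral palsy) reflect altered *neural control* or
merely emerge from altered *biomechanics* (slower, more asymmetric, wider
steps).  One way to probe this is to analyze muscle activations across many
systematically varied walking behaviors with the identical module pipeline
used on experimental EMG, and ask whether a single module set suffices.

`motormod` implements that pipeline for anyone working with nonnegative
muscle-activation matrices on a normalized 101-point gait cycle — from
musculoskeletal simulation outputs (OpenSim storage files) or processed
EMG envelopes (CSV):

* **Extraction** — nonnegative matrix factorization E ≈ W·C (Lee–Seung
  multiplicative updates, multi-restart), with the module number *n* chosen
  as the smallest for which
  `VAF = 1 − Σ(E − W·C)² / ΣE²` exceeds a threshold (0.95, with 0.90 as a
  sensitivity setting).
* **Structure comparison** — Pearson correlation between module weight
  vectors, put in one-to-one correspondence by optimal assignment; applied
  across conditions and between legs.
* **Fixed-module reconstruction** — given reference modules W_ref, solve
  `min ‖W_ref·C − E_target‖_F  s.t. C ≥ 0` exactly (one NNLS per grid
  point) and score it with VAF.
* **Recruitment metrics** — peak activation, circular-statistics center of
  activity (CoA), and dynamic-time-warping (DTW) distance between
  activation patterns.
* **Synthetic generator** — gait activations with planted modular structure
  over a 27-condition grid (speeds 0.8/1.1/1.45 m/s; step-length asymmetry
  0/15/30 %; step widths 0.1/0.2/0.3 m; both legs; a 43-muscle full set and
  an 8-muscle EMG-like subset), so every pipeline stage is verifiable by
  parameter recovery.

## Worked example

```python
import motormod as mm

# Planted 3-module ground truth for the 8-muscle subset, noise sd 0.02
truth = mm.make_ground_truth(mm.SUBSET_8, seed=1)
ref = mm.reference_condition("right")          # 1.1 m/s, symmetric, 0.1 m
E = mm.synthesize_activations(truth, ref)      # 8 x 101, nonnegative

n, curve = mm.select_module_number(E, threshold=0.95, n_max=8,
                                   replicates=10, seed=0)
print(n, curve.vaf_at_n.round(4))
res = mm.nmf_decompose(E, n, seed=0, replicates=10)
pairing = mm.match_modules(truth.W_true, res.W)
print(res.vaf.__round__(4), pairing.r_values.round(3))
```

prints

```
3 [0.6662 0.899  0.9913 0.9936 0.9956 0.9972 0.9986 0.9997]
0.9913 [1.    0.999 0.994]
```

Two modules leave 10 % of the signal unexplained, three cross the 95 % VAF
threshold (VAF 0.991), and the extracted weight vectors match the planted
ones with Pearson r ≥ 0.99 — the generator's three modules are recovered.

The same flow from the shell:

```bash
motormod simulate --out sim/ --seed 1                  # 54 activation files
motormod analyze  --out tables/ --seed 1               # full study tables
motormod compare  --reference sim/speed1.1_asym0.00_width0.1_right.csv \
                  --target    sim/speed1.45_asym0.00_width0.1_right.csv
```

`analyze` writes tidy CSV tables (module number per threshold, structure
similarity, reconstruction VAF, per-module peak/CoA/DTW, bilateral
similarity) plus a JSON run log with the seed, config hash and VAF curves.

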