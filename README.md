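# tractstim

Tract-guided programming support for subthalamic-nucleus deep brain
stimulation (STN-DBS).

After a patient receives a directional DBS lead, clinicians run a
*monopolar review*: for each contact the amplitude is swept from 1 to 8 mA
in 0.5 mA steps to find the **effect threshold** (lowest amplitude fully
suppressing wrist rigidity) and the **side-effect threshold** (lowest
amplitude causing persistent capsular muscle contractions). With
8-contact directional leads this is slow. `tractstim` implements the
tractography-based shortcut: relate the *activation* of two white-matter
pathways — the hyperdirect pathway (HDP), whose stimulation mediates the
therapeutic effect, and the corticospinal tract (CST), whose stimulation
causes the capsular side effects — to the review outcomes, and use the
fitted models to suggest stimulation parameters.

## The model

For a stimulation setting, the volume of tissue activated (VTA) is the
region where the electric field exceeds a threshold. The package uses the
homogeneous point-source kernel: the field of a current *I* in a medium of
conductivity σ is E(r) = I / (4π σ r²), so thresholding at E_t activates a
sphere of radius

    r(I) = sqrt(I / (4π σ E_t)),       r(1 mA) ≈ 1.10 mm

with σ = 0.33 S/m (grey matter) and E_t = 0.2 V/mm. Segmented contacts
clip the sphere to an angular sector about the contact's outward normal;
pseudorings (the three segments of a level driven together) act as rings.

For a pathway with streamlines *s* carrying SIFT2-style weights *w_s*, the
**activation fraction** of a VTA *V* is

    a(V) = Σ_{s ∩ V ≠ ∅} w_s / Σ_s w_s ,

streamline-segment intersection being computed exactly. Two binary
logistic **stimulation models** are fitted,

    p(effect | a) = 1 / (1 + exp(−(β₀ + β₁ a))),

one for the HDP (outcome: full rigidity reduction) and one for the CST
(outcome: capsular side effects). Training data come from the review:
activation at 0.5 mA is a "no effect" sample for every tested
configuration; activation at the recorded threshold is an "effect" sample
(censored thresholds, written `">8"`, contribute no positive). The inverse
L2 penalty is chosen by subject-grouped inner cross-validation inside a
leave-one-subject-out (LOSO) outer loop.

Each held-out lead then gets *suggestions*: per configuration, the lowest
grid amplitude classified "effect" (an effect threshold from the HDP
model, a side-effect threshold from the CST model), and a best/worst level
and contact under three strategies — lowest effect threshold (*initial*),
lowest effect threshold among configurations whose effect comes no more
than 1 mA after the side effect (*combined*), and widest therapeutic
window, side-effect minus effect threshold (*window*). Agreement with the
clinical review is scored with balanced accuracy
0.5·(TP/(TP+FN) + TN/(TN+FP)) — the classes are heavily unbalanced (one
best level in four, one best contact in eight) — tested against chance by
permuting the suggestion vector (right-tailed, 100 000 permutations), plus
absolute/signed threshold errors in mA.

A synthetic-cohort generator (`tractstim.synthetic_cohort`) builds the
whole study world — ellipsoidal STN, HDP bundle converging on its
dorsolateral sector, CST tube descending posterolateral to it, jittered
directional leads, and reviews simulated from known ground-truth logistic
responses — so every stage is testable without patient data.

## Worked example

`examples/03_stimulation_models.py` generates an 8-subject cohort with
ground-truth boundaries a₅₀ = 0.10 (HDP) and 0.01 (CST) and fits the
models with nested LOSO:

```
HDP: 281 samples (124 effect), 8 folds
  mean held-out accuracy 0.827 (95% CI 0.779-0.874)
  pooled 50% boundary 0.1109 (generating truth 0.1000)
CST: 242 samples (85 effect), 8 folds
  mean held-out accuracy 0.975 (95% CI 0.959-0.991)
  pooled 50% boundary 0.0101 (generating truth 0.0100)
```

The pooled boundary is the mean over folds of −β₀/β₁ — the activation
fraction at 50% predicted probability. Recovery of the generating values
means the censored, noisy review still identifies the dose-response. The
other examples show the lead geometry and VTA kernel (`01`), activation
profiles over the amplitude grid (`02`), and suggestions plus their
evaluation (`04`). A thin CLI covers the same pipeline from the shell:

```bash
tractstim synth --out cohort/ --seed 1            # TCK + weights + CSVs
tractstim run-all --bundles cohort/ --leads cohort/leads.csv \
    --reviews cohort/reviews.csv --out run/ --seed 1
```

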