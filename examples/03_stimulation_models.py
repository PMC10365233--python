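"""Fitting the HDP and CST stimulation models with leave-one-subject-out CV.

Generates a small synthetic cohort with known ground-truth logistic
responses (50% effect probability at 10% HDP activation, 1% CST
activation), builds the monopolar-review training set — "no effect" at
0.5 mA, "effect" at the recorded thresholds — and reports how well the
nested cross-validated logistic models recover the generating boundaries.
"""

from tractstim import (SyntheticParams, activation_at_probability,
                       build_training_samples, generate_cohort, loso_cv)

params = SyntheticParams(seed=7, n_subjects=8, n_streamlines_hdp=200,
                         n_streamlines_cst=600)
cohort = generate_cohort(params)

act_map = {}
for lid, table in cohort.activation_tables.items():
    for pathway, cfgs in table.items():
        for cfg, prof in cfgs.items():
            for amp, frac in prof.items():
                act_map[(lid, cfg, amp, pathway)] = frac

for pathway in ("HDP", "CST"):
    samples = build_training_samples(cohort.reviews, act_map, pathway)
    cv = loso_cv(samples)
    truth = cohort.true_models[pathway].boundary
    n_pos = sum(s.label == "effect" for s in samples)
    print(f"{pathway}: {len(samples)} samples ({n_pos} effect), "
          f"{len(cv.folds)} folds")
    print(f"  mean held-out accuracy {cv.mean_accuracy:.3f} "
          f"(95% CI {cv.ci95[0]:.3f}-{cv.ci95[1]:.3f})")
    print(f"  pooled 50% boundary {cv.pooled_boundary:.4f} "
          f"(generating truth {truth:.4f})")
    model = cv.folds[0].model
    print(f"  fold-1 activation at p=0.95: "
          f"{activation_at_probability(model, 0.95):.4f}")

print(
    "\nThe pooled boundary is the mean over folds of -beta0/beta1, the\n"
    "activation fraction at 50% predicted probability; close agreement\n"
    "with the generating truth means the review carries enough signal to\n"
    "identify the dose-response despite censoring and threshold noise."
)
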