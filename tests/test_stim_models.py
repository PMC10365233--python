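"""Training-set construction, logistic fits, and leave-one-subject-out CV."""

import math

import numpy as np
import pytest

from tractstim.stim_models import (
    ActivationSample,
    StimulationModel,
    activation_at_probability,
    build_training_samples,
    fit_stim_model,
    loso_cv,
    predict_class,
)
from tractstim.tract_io import ReviewRecord


def act_map_for(lead_id, config_ids, hdp=0.02, cst=0.001):
    """Activation lookup covering 0.5 mA and the whole 1-8 grid."""
    out = {}
    for cfg in config_ids:
        for k in range(1, 17):
            amp = round(0.5 * k, 1)
            out[(lead_id, cfg, amp, "HDP")] = min(1.0, hdp * k)
            out[(lead_id, cfg, amp, "CST")] = min(1.0, cst * k)
    return out


class TestBuildTrainingSamples:
    def test_full_lead_gives_negatives_and_positives(self):
        cfgs = ["L1", "L2", "L3", "L4"]
        reviews = [ReviewRecord("S01", "A", c, 2.0, 3.0) for c in cfgs]
        acts = act_map_for("A", cfgs)
        for pathway in ("HDP", "CST"):
            samples = build_training_samples(reviews, acts, pathway)
            assert len(samples) == 8
            assert sum(s.label == "no_effect" for s in samples) == 4
            assert all(s.amplitude == 0.5 for s in samples
                       if s.label == "no_effect")

    def test_censored_threshold_contributes_negative_only(self):
        reviews = [ReviewRecord("S01", "A", "L1", 2.0, None,
                                side_effect_censored=True)]
        acts = act_map_for("A", ["L1"])
        cst = build_training_samples(reviews, acts, "CST")
        assert len(cst) == 1 and cst[0].label == "no_effect"
        hdp = build_training_samples(reviews, acts, "HDP")
        assert len(hdp) == 2

    def test_untested_config_skipped(self):
        reviews = [ReviewRecord("S01", "A", "L1", tested=False)]
        assert build_training_samples(reviews, {}, "HDP") == []

    def test_sample_values(self):
        reviews = [ReviewRecord("S01", "A", "L1", 2.0, None,
                                side_effect_censored=True)]
        acts = {("A", "L1", 0.5, "HDP"): 0.01, ("A", "L1", 2.0, "HDP"): 0.30}
        samples = build_training_samples(reviews, acts, "HDP")
        assert [(s.activation, s.label) for s in samples] == \
            [(0.01, "no_effect"), (0.30, "effect")]

    def test_missing_activation_names_config(self):
        reviews = [ReviewRecord("S01", "A", "L2", 2.0, 3.0)]
        acts = {("A", "L2", 0.5, "HDP"): 0.01}
        with pytest.raises(KeyError, match="L2"):
            build_training_samples(reviews, acts, "HDP")


def toy_samples(points, subject="S01"):
    return [ActivationSample(subject, "A", "L1", 1.0, "HDP", a,
                             "effect" if y else "no_effect")
            for a, y in points]


class TestFitStimModel:
    def test_separated_boundary_brackets(self):
        samples = toy_samples([(0.0, 0), (0.05, 0), (0.6, 1), (0.7, 1)])
        model = fit_stim_model(samples, reg_grid=[1.0])
        assert 0.05 < model.boundary < 0.6
        assert model.beta1 > 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_stim_model(toy_samples([(0.1, 0), (0.2, 0)]))

    def test_duplication_invariance(self):
        """Duplicating every sample leaves the decision boundary unchanged
        (exactly so for the maximum-likelihood fit; tested in the
        weak-penalty regime where the fit approaches it)."""
        pts = [(0.02, 0), (0.08, 0), (0.15, 1), (0.3, 1), (0.12, 0),
               (0.11, 1)]
        m1 = fit_stim_model(toy_samples(pts), reg_grid=[1e6])
        m2 = fit_stim_model(toy_samples(pts + pts), reg_grid=[1e6])
        assert m1.boundary == pytest.approx(m2.boundary, abs=1e-4)

    def test_recovers_generating_boundary(self):
        """Labels drawn from p(a) = logistic(-6 + 12 a): the fitted 50%
        point lands near the true 0.5."""
        rng = np.random.default_rng(123)
        a = rng.uniform(0, 1, 2000)
        p = 1 / (1 + np.exp(-(-6 + 12 * a)))
        y = rng.uniform(size=2000) < p
        samples = [
            ActivationSample(f"S{i % 10}", "A", "L1", 1.0, "HDP",
                             float(ai), "effect" if yi else "no_effect")
            for i, (ai, yi) in enumerate(zip(a, y))
        ]
        model = fit_stim_model(samples, reg_grid=[1000.0])
        assert model.boundary == pytest.approx(0.5, abs=0.03)


class TestPredictAndInverse:
    model = StimulationModel("HDP", beta0=-9.2, beta1=18.4)

    def test_boundary_tie_goes_to_effect(self):
        p, label = predict_class(self.model, self.model.boundary)
        assert p == pytest.approx(0.5, abs=1e-12)
        assert label == "effect"

    def test_low_activation_is_no_effect(self):
        p, label = predict_class(self.model, 0.0)
        assert label == "no_effect" and p < 1e-3

    def test_closed_form_probability(self):
        p, label = predict_class(self.model, 0.75)
        assert p == pytest.approx(1 / (1 + math.exp(-4.6)), rel=1e-12)
        assert label == "effect"

    def test_inverse_at_half(self):
        assert activation_at_probability(self.model, 0.5) == pytest.approx(
            self.model.boundary, rel=1e-12)

    def test_inverse_closed_form(self):
        m = StimulationModel("HDP", beta0=-6.0, beta1=12.0)
        assert activation_at_probability(m, 0.99) == pytest.approx(
            (math.log(0.99 / 0.01) + 6) / 12, rel=1e-9)

    def test_inverse_continuous_at_half(self):
        lo = activation_at_probability(self.model, 0.5 - 1e-9)
        hi = activation_at_probability(self.model, 0.5 + 1e-9)
        assert hi - lo == pytest.approx(0.0, abs=1e-6)

    def test_probability_monotone_for_positive_slope(self):
        a = np.linspace(0, 1, 101)
        p = self.model.probability(a)
        assert np.all(np.diff(p) > 0)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            activation_at_probability(self.model, 1.0)


def synthetic_cv_samples(rng, n_subjects=20, per_subject=16,
                         beta0=-8.0, beta1=80.0, noise=True):
    samples = []
    for i in range(n_subjects):
        sid = f"S{i:02d}"
        a = rng.uniform(0, 0.3, per_subject)
        z = beta0 + beta1 * a
        p = 1 / (1 + np.exp(-z))
        y = (rng.uniform(size=per_subject) < p) if noise else (p >= 0.5)
        samples += [
            ActivationSample(sid, f"{sid}_R", "L1", 1.0, "HDP", float(ai),
                             "effect" if yi else "no_effect")
            for ai, yi in zip(a, y)
        ]
    return samples


class TestLosoCv:
    def test_structure_one_fold_per_subject(self):
        rng = np.random.default_rng(5)
        samples = synthetic_cv_samples(rng, n_subjects=8)
        result = loso_cv(samples, reg_grid=[10.0])
        assert len(result.folds) == 8
        held = {f.held_out_subject for f in result.folds}
        assert held == {s.subject_id for s in samples}

    def test_no_leakage_of_held_out_subject(self):
        rng = np.random.default_rng(6)
        samples = synthetic_cv_samples(rng, n_subjects=6)
        result = loso_cv(samples, reg_grid=[10.0])
        for fold in result.folds:
            n_test = sum(s.subject_id == fold.held_out_subject
                         for s in samples)
            assert len(fold.predicted_labels) == n_test

    def test_uninformative_labels_score_near_class_frequency(self):
        rng = np.random.default_rng(7)
        samples = []
        for i in range(12):
            sid = f"S{i:02d}"
            for _ in range(20):
                samples.append(ActivationSample(
                    sid, sid, "L1", 1.0, "HDP", float(rng.uniform(0, 1)),
                    "effect" if rng.uniform() < 0.7 else "no_effect"))
        result = loso_cv(samples, reg_grid=[1.0])
        assert result.mean_accuracy == pytest.approx(0.7, abs=0.08)

    def test_noiseless_steep_truth_is_learnable(self):
        rng = np.random.default_rng(8)
        samples = synthetic_cv_samples(rng, noise=False)
        result = loso_cv(samples, reg_grid=[100.0, 1000.0])
        assert result.mean_accuracy > 0.95

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(9)
        samples = synthetic_cv_samples(rng, n_subjects=2)
        with pytest.raises(ValueError, match="3 subjects"):
            loso_cv(samples)
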