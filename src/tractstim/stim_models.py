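"""Logistic stimulation models and nested leave-one-subject-out CV.

One model per pathway: the hyperdirect pathway (HDP) model maps HDP
activation fraction to the probability of full therapeutic effect; the
corticospinal tract (CST) model maps CST activation to the probability of
persistent capsular side effects.

Training samples come from the monopolar review: for every tested
configuration the activation at 0.5 mA is a "no effect" sample (minimal
activation, below any clinical response), and — when the relevant
threshold was reached within the sweep — the activation at the recorded
threshold amplitude is an "effect" sample.  Censored thresholds (">8")
contribute no positive sample.

Fitting is L2-penalised logistic regression; the inverse-penalty strength
is chosen by subject-grouped inner cross-validation maximising balanced
accuracy.  The outer loop is leave-one-subject-out.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, GroupKFold

from .tract_io import ReviewRecord

__all__ = [
    "ActivationSample",
    "StimulationModel",
    "FoldResult",
    "CVResult",
    "DEFAULT_REG_GRID",
    "build_training_samples",
    "fit_stim_model",
    "predict_class",
    "activation_at_probability",
    "loso_cv",
]

#: Inverse L2 regularisation grid (sklearn's C), log-spaced.
DEFAULT_REG_GRID = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)

PATHWAYS = ("HDP", "CST")


@dataclass
class ActivationSample:
    """One (activation fraction, binary outcome) training/evaluation sample."""

    subject_id: str
    lead_id: str
    config_id: str
    amplitude: float
    pathway: str
    activation: float
    label: str | None = None    # "effect" | "no_effect"

    def __post_init__(self) -> None:
        if not 0.0 <= self.activation <= 1.0:
            raise ValueError("activation must lie in [0, 1]")
        if self.label not in (None, "effect", "no_effect"):
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class StimulationModel:
    """1-D logistic model: p(effect | a) = 1 / (1 + exp(-(b0 + b1 a)))."""

    pathway: str
    beta0: float
    beta1: float
    reg_strength: float = math.nan   # inverse L2 penalty chosen by inner CV
    class_cutoff: float = 0.5

    def probability(self, activation: float | np.ndarray) -> float | np.ndarray:
        z = self.beta0 + self.beta1 * np.asarray(activation, dtype=float)
        return 1.0 / (1.0 + np.exp(-z))

    @property
    def boundary(self) -> float:
        """Activation at 50% probability: -beta0 / beta1."""
        if self.beta1 == 0:
            raise ZeroDivisionError("beta1 is zero; the boundary is undefined")
        return -self.beta0 / self.beta1

    def to_card(self) -> dict:
        """Model-card dict: coefficients plus the inverse at key probabilities."""
        card = {
            "pathway": self.pathway,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "odds_ratio": math.exp(self.beta1),
            "reg_strength": self.reg_strength,
            "boundary": self.boundary,
        }
        for p in (0.5, 0.95, 0.99):
            card[f"activation_at_p{p:g}"] = activation_at_probability(self, p)
        return card


def build_training_samples(
    reviews: Sequence[ReviewRecord],
    activations: Mapping[tuple[str, str, float, str], float],
    pathway: str,
) -> list[ActivationSample]:
    """Assemble the logistic training set for one pathway.

    ``activations`` maps ``(lead_id, config_id, amplitude_mA, pathway)`` to
    an activation fraction.  For every tested configuration: a negative
    sample at 0.5 mA, and a positive at the relevant threshold (effect for
    HDP, side effect for CST) when that threshold is uncensored.
    """
    if pathway not in PATHWAYS:
        raise ValueError(f"unknown pathway {pathway!r}")
    samples: list[ActivationSample] = []
    for rec in reviews:
        if not rec.tested:
            continue
        key0 = (rec.lead_id, rec.config_id, 0.5, pathway)
        if key0 not in activations:
            raise KeyError(
                f"no {pathway} activation at 0.5 mA for "
                f"{rec.lead_id}/{rec.config_id}"
            )
        samples.append(ActivationSample(
            rec.subject_id, rec.lead_id, rec.config_id, 0.5, pathway,
            activations[key0], "no_effect"))
        threshold = (rec.effect_threshold if pathway == "HDP"
                     else rec.side_effect_threshold)
        if threshold is None:
            continue
        key = (rec.lead_id, rec.config_id, float(threshold), pathway)
        if key not in activations:
            raise KeyError(
                f"{pathway} activation missing at threshold {threshold} mA "
                f"for {rec.lead_id}/{rec.config_id}"
            )
        samples.append(ActivationSample(
            rec.subject_id, rec.lead_id, rec.config_id, float(threshold),
            pathway, activations[key], "effect"))
    return samples


def _design(samples: Sequence[ActivationSample]):
    X = np.array([[s.activation] for s in samples])
    y = np.array([1 if s.label == "effect" else 0 for s in samples])
    groups = np.array([s.subject_id for s in samples])
    return X, y, groups


def fit_stim_model(
    samples: Sequence[ActivationSample],
    reg_grid: Sequence[float] = DEFAULT_REG_GRID,
    inner_folds: int = 5,
    pathway: str | None = None,
) -> StimulationModel:
    """Fit one pathway's logistic model with inner-CV penalty selection.

    The inner split is grouped by subject (up to ``inner_folds`` groups);
    with too few subjects for a grouped split, the middle of ``reg_grid``
    is used directly.
    """
    if not samples:
        raise ValueError("no training samples")
    X, y, groups = _design(samples)
    if len(np.unique(y)) < 2:
        raise ValueError("training samples contain a single class")
    pathway = pathway or samples[0].pathway
    n_groups = len(np.unique(groups))
    # default penalty is the L2 ridge; C is tuned below
    base = LogisticRegression(solver="lbfgs", max_iter=5000)
    if n_groups >= 2 and len(reg_grid) > 1:
        n_splits = min(inner_folds, n_groups)
        search = GridSearchCV(
            base, {"C": list(reg_grid)},
            cv=GroupKFold(n_splits=n_splits),
            scoring="balanced_accuracy",
            error_score="raise",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            search.fit(X, y, groups=groups)
        clf = search.best_estimator_
        reg = float(search.best_params_["C"])
    else:
        reg = float(reg_grid[len(reg_grid) // 2])
        clf = base.set_params(C=reg).fit(X, y)
    return StimulationModel(
        pathway=pathway,
        beta0=float(clf.intercept_[0]),
        beta1=float(clf.coef_[0, 0]),
        reg_strength=reg,
    )


def predict_class(model: StimulationModel,
                  activation: float) -> tuple[float, str]:
    """Probability of effect and the binary label (ties go to "effect")."""
    if not 0.0 <= activation <= 1.0:
        raise ValueError("activation must lie in [0, 1]")
    p = float(model.probability(activation))
    label = "effect" if p >= model.class_cutoff else "no_effect"
    return p, label


def activation_at_probability(model: StimulationModel, p: float) -> float:
    """Inverse of the logistic curve: activation giving probability ``p``."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly inside (0, 1)")
    if model.beta1 == 0:
        raise ZeroDivisionError("beta1 is zero; the inverse is undefined")
    return (math.log(p / (1.0 - p)) - model.beta0) / model.beta1


@dataclass
class FoldResult:
    held_out_subject: str
    model: StimulationModel
    predicted_labels: list[str]
    true_labels: list[str]
    accuracy: float


@dataclass
class CVResult:
    pathway: str
    folds: list[FoldResult]
    mean_accuracy: float
    ci95: tuple[float, float]

    @property
    def pooled_boundary(self) -> float:
        """Mean of the per-fold 50%-probability activations."""
        return float(np.mean([f.model.boundary for f in self.folds]))

    def fold_for_subject(self, subject_id: str) -> FoldResult:
        for f in self.folds:
            if f.held_out_subject == subject_id:
                return f
        raise KeyError(subject_id)


def loso_cv(
    samples: Sequence[ActivationSample],
    reg_grid: Sequence[float] = DEFAULT_REG_GRID,
    inner_folds: int = 5,
) -> CVResult:
    """Nested leave-one-subject-out cross-validation for one pathway.

    One outer fold per subject; the inner penalty search sees only the
    training subjects.  Folds whose training set collapses to one class
    are skipped with a warning.  Aggregate accuracy carries a normal
    95% confidence interval across folds.
    """
    subjects = sorted({s.subject_id for s in samples})
    if len(subjects) < 3:
        raise ValueError("leave-one-subject-out needs at least 3 subjects")
    folds: list[FoldResult] = []
    for held_out in subjects:
        train = [s for s in samples if s.subject_id != held_out]
        test = [s for s in samples if s.subject_id == held_out]
        if not test:
            continue
        y_train = {s.label for s in train}
        if len(y_train) < 2:
            warnings.warn(
                f"fold {held_out}: single-class training set, skipped")
            continue
        model = fit_stim_model(train, reg_grid, inner_folds)
        preds = [predict_class(model, s.activation)[1] for s in test]
        truth = [s.label for s in test]
        acc = float(np.mean([p == t for p, t in zip(preds, truth)]))
        folds.append(FoldResult(held_out, model, preds, truth, acc))
    if not folds:
        raise ValueError("no usable folds")
    accs = np.array([f.accuracy for f in folds])
    mean = float(accs.mean())
    sem = float(accs.std(ddof=1) / math.sqrt(len(accs))) if len(accs) > 1 else 0.0
    ci = (mean - 1.96 * sem, mean + 1.96 * sem)
    return CVResult(pathway=samples[0].pathway, folds=folds,
                    mean_accuracy=mean, ci95=ci)
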