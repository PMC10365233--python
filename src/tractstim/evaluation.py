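"""Scoring suggestions against the clinical monopolar review.

The best/worst-label task is heavily unbalanced (one best level in four,
one best contact in eight, per lead), so agreement is summarised as
balanced accuracy — the mean of sensitivity and specificity — and tested
against chance with a right-tailed permutation test that shuffles the
model's suggestion vector.  Threshold agreement is summarised by absolute
and signed errors in mA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .lead_vta import CONTACT_CONFIGS, LEVEL_CONFIGS, LeadModel, contact_frames

__all__ = [
    "ConfusionCounts",
    "PermutationResult",
    "balanced_accuracy",
    "confusion_from_vectors",
    "label_vectors",
    "permutation_test",
    "threshold_errors",
    "contact_distance",
]


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class PermutationResult:
    observed_statistic: float
    n_permutations: int
    p_value: float
    seed: int


def balanced_accuracy(c: ConfusionCounts) -> float:
    """0.5 * (sensitivity + specificity).

    Undefined (raises) when either class is empty.
    """
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ZeroDivisionError(
            "balanced accuracy undefined: one class has no members")
    return 0.5 * (c.tp / (c.tp + c.fn) + c.tn / (c.tn + c.fp))


def confusion_from_vectors(suggested: np.ndarray,
                           clinical: np.ndarray) -> ConfusionCounts:
    suggested = np.asarray(suggested, dtype=bool)
    clinical = np.asarray(clinical, dtype=bool)
    if suggested.shape != clinical.shape:
        raise ValueError("vectors must have the same length")
    return ConfusionCounts(
        tp=int(np.sum(suggested & clinical)),
        fn=int(np.sum(~suggested & clinical)),
        tn=int(np.sum(~suggested & ~clinical)),
        fp=int(np.sum(suggested & ~clinical)),
    )


def label_vectors(suggested_labels: Mapping[str, str | None],
                  clinical_labels: Mapping[str, str | None],
                  granularity: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Expand per-lead best/worst labels into paired binary vectors.

    Each lead contributes 4 (level) or 8 (contact) paired entries, one per
    candidate configuration, concatenated across leads in sorted lead
    order.  Leads without a clinical label are dropped with a warning; a
    lead whose suggestion is ``None`` contributes all-zero suggestion
    entries.  Returns (suggested, clinical, leads_used).
    """
    if granularity == "level":
        candidates = LEVEL_CONFIGS
    elif granularity == "contact":
        candidates = CONTACT_CONFIGS
    else:
        raise ValueError("granularity must be 'level' or 'contact'")
    sugg_bits: list[int] = []
    clin_bits: list[int] = []
    used: list[str] = []
    for lead_id in sorted(clinical_labels):
        clin = clinical_labels[lead_id]
        if clin is None:
            warnings.warn(f"lead {lead_id}: no clinical label, dropped")
            continue
        sugg = suggested_labels.get(lead_id)
        used.append(lead_id)
        for cfg in candidates:
            sugg_bits.append(1 if sugg == cfg else 0)
            clin_bits.append(1 if clin == cfg else 0)
    return (np.array(sugg_bits, dtype=int), np.array(clin_bits, dtype=int),
            used)


def permutation_test(suggested: np.ndarray, clinical: np.ndarray,
                     n_perm: int = 100_000, seed: int = 0,
                     mode: str = "global", block_size: int | None = None,
                     add_one: bool = True,
                     chunk: int = 10_000) -> PermutationResult:
    """Right-tailed permutation test of balanced accuracy.

    The suggestion vector is shuffled uniformly (``mode='global'``, the
    default) or within consecutive per-lead blocks of ``block_size``
    entries (``mode='within_lead'``).  With ``add_one`` the p-value uses
    the add-one correction p = (1 + #{stat >= observed}) / (1 + n), which
    never returns 0; ``add_one=False`` gives the plain fraction.
    """
    suggested = np.asarray(suggested, dtype=int)
    clinical = np.asarray(clinical, dtype=int)
    if suggested.shape != clinical.shape:
        raise ValueError("vectors must have the same length")
    observed = balanced_accuracy(confusion_from_vectors(suggested, clinical))
    if mode == "within_lead" and not block_size:
        raise ValueError("within_lead mode needs block_size")
    rng = np.random.default_rng(seed)
    n = len(suggested)
    n_pos = int(clinical.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ZeroDivisionError("clinical vector has a single class")
    n_extreme = 0
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        if mode == "global":
            perm = rng.permuted(np.tile(suggested, (m, 1)), axis=1)
        elif mode == "within_lead":
            blocks = suggested.reshape(-1, block_size)
            perm = np.stack([
                rng.permuted(np.tile(b, (m, 1)), axis=1).T for b in blocks
            ])  # (n_blocks, block, m)
            perm = perm.transpose(2, 0, 1).reshape(m, n)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        tp = perm @ clinical
        pos = perm.sum(axis=1)
        sens = tp / n_pos
        spec = (n_neg - (pos - tp)) / n_neg
        stats = 0.5 * (sens + spec)
        n_extreme += int(np.sum(stats >= observed))
        done += m
    if add_one:
        p = (1 + n_extreme) / (1 + n_perm)
    else:
        p = n_extreme / n_perm
    return PermutationResult(observed_statistic=float(observed),
                             n_permutations=n_perm, p_value=float(p),
                             seed=seed)


def threshold_errors(suggested: Sequence[float | None],
                     clinical: Sequence[float | None],
                     lead_ids: Sequence[str] | None = None) -> dict:
    """Signed and absolute suggestion errors over paired thresholds.

    Pairs with either side censored (``None``) are excluded; the count of
    exclusions is reported.  ``signed = suggested - clinical``.
    """
    if len(suggested) != len(clinical):
        raise ValueError("paired threshold lists must have the same length")
    if lead_ids is not None and len(lead_ids) != len(suggested):
        raise ValueError("lead_ids must pair with the thresholds")
    signed: list[float] = []
    absolute: list[float] = []
    groups: dict[str, list[float]] = {}
    n_excluded = 0
    for i, (s, c) in enumerate(zip(suggested, clinical)):
        if s is None or c is None:
            n_excluded += 1
            continue
        d = float(s) - float(c)
        signed.append(d)
        absolute.append(abs(d))
        if lead_ids is not None:
            groups.setdefault(lead_ids[i], []).append(abs(d))
    if not signed:
        raise ValueError("no uncensored threshold pairs")
    return {
        "absolute": absolute,
        "signed": signed,
        "median_abs": float(np.median(absolute)),
        "median_signed": float(np.median(signed)),
        "n_pairs": len(signed),
        "n_excluded": n_excluded,
        "per_lead_abs": groups,
    }


def contact_distance(suggested_contact: str, clinical_contact: str,
                     lead: LeadModel) -> dict:
    """Same-level flag and centroid distance between two contacts."""
    frames = {f"C{f.contact_id}": f for f in contact_frames(lead)}
    fa = frames[suggested_contact]
    fb = frames[clinical_contact]
    return {
        "same_level": fa.level == fb.level,
        "euclidean_mm": float(np.linalg.norm(fa.centroid - fb.centroid)),
    }
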