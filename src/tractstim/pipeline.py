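"""End-to-end orchestration: cohort -> activations -> models -> suggestions -> scores.

The pipeline mirrors a retrospective programming study: activation tables
are computed for every lead configuration on the amplitude grid, logistic
stimulation models are fitted with nested leave-one-subject-out
cross-validation, each lead's suggestions come from the fold in which its
subject was held out, and the suggestions are scored against the
(simulated or supplied) monopolar review.

Inputs are either an in-memory :class:`~tractstim.synthetic_cohort.SyntheticCohort`
or files on disk (TCK bundles + weights, a lead-pose CSV and a review CSV);
outputs are plain CSV/JSON artifacts, each stamped with the seed and a
hash of the configuration so reruns are attributable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import (balanced_accuracy, confusion_from_vectors,
                         label_vectors, permutation_test, threshold_errors)
from .lead_vta import ALL_CONFIGS, CONTACT_CONFIGS, LEVEL_CONFIGS, LeadModel, \
    VTAParams
from .stim_models import (DEFAULT_REG_GRID, CVResult, build_training_samples,
                          loso_cv)
from .suggestion import (ConfigThresholds, SuggestionResult,
                         config_thresholds, suggest_lead)
from .synthetic_cohort import (SyntheticCohort, SyntheticParams,
                               generate_cohort, lead_activation_table)
from .tract_io import (AMPLITUDE_GRID, ReviewRecord, load_bundle,
                       read_lead_poses, read_reviews, write_report)

logger = logging.getLogger("tractstim")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "clinical_labels"]

STRATEGIES = ("initial", "combined", "window")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str | None = None
    # synthetic input (used when the path triple below is not given)
    synthetic: SyntheticParams | None = None
    # file inputs
    bundles_dir: str | None = None       # {lead_id}_{pathway}.tck + .weights.txt
    leads_csv: str | None = None
    reviews_csv: str | None = None
    vta_params: VTAParams = field(default_factory=VTAParams)
    amplitude_grid: tuple[float, ...] = AMPLITUDE_GRID
    reg_grid: tuple[float, ...] = DEFAULT_REG_GRID
    strategies: tuple[str, ...] = STRATEGIES
    n_permutations: int = 100_000
    permutation_mode: str = "global"
    seed: int = 0

    def config_hash(self) -> str:
        """Hash of the analysis configuration (the output path is excluded
        so reruns into different directories are recognisably identical)."""
        fields = _jsonable(asdict(self))
        fields.pop("out_dir", None)
        blob = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return float(obj)
    return obj


@dataclass
class PipelineResult:
    config: RunConfig
    activations: pd.DataFrame
    cv_results: dict[str, CVResult]
    suggestions: dict[str, dict[str, SuggestionResult]]   # strategy -> lead
    evaluation: dict
    threshold_error_summary: dict


def clinical_labels(reviews: Sequence[ReviewRecord], granularity: str,
                    which: str) -> dict[str, str | None]:
    """Clinical best/worst label per lead: the lowest-threshold config.

    ``which='best'`` uses effect thresholds, ``'worst'`` side-effect
    thresholds; censored/untested configs never win.  Ties fall to the
    wider (best) / narrower (worst) clinical window, then the more distal
    config.
    """
    candidates = LEVEL_CONFIGS if granularity == "level" else CONTACT_CONFIGS
    by_lead: dict[str, list[ReviewRecord]] = {}
    for r in reviews:
        by_lead.setdefault(r.lead_id, []).append(r)
    labels: dict[str, str | None] = {}
    for lead_id, recs in by_lead.items():
        scored = []
        for r in recs:
            if not r.tested or r.config_id not in candidates:
                continue
            thr = (r.effect_threshold if which == "best"
                   else r.side_effect_threshold)
            if thr is None:
                continue
            eff = r.effect_threshold
            se = (r.side_effect_threshold
                  if r.side_effect_threshold is not None else 8.5)
            window = (se - eff) if eff is not None else None
            if which == "best":
                tie = -(window if window is not None else -1e9)
            else:
                tie = window if window is not None else 1e9
            scored.append((thr, tie, int(r.config_id[1]), r.config_id))
        labels[lead_id] = (sorted(scored)[0][3] if scored else None)
    return labels


def _load_cohort_from_files(config: RunConfig):
    poses = read_lead_poses(config.leads_csv)
    reviews = read_reviews(config.reviews_csv)
    leads: dict[str, LeadModel] = {}
    lead_subject: dict[str, str] = {}
    bundles: dict[str, dict] = {}
    bdir = Path(config.bundles_dir)
    for pose in poses:
        lead_id = pose["lead_id"]
        leads[lead_id] = LeadModel(tip=pose["tip"], axis=pose["axis"],
                                   rotation=pose["rotation"])
        lead_subject[lead_id] = pose["subject_id"]
        hemi = "left" if lead_id.endswith("L") else "right"
        pair = {}
        for pathway in ("HDP", "CST"):
            tck = bdir / f"{lead_id}_{pathway}.tck"
            wts = bdir / f"{lead_id}_{pathway}.weights.txt"
            pair[pathway] = load_bundle(
                tck, wts if wts.exists() else None, pathway, hemi)
        bundles[lead_id] = pair
    return leads, lead_subject, bundles, reviews


def run_pipeline(config: RunConfig,
                 cohort: SyntheticCohort | None = None) -> PipelineResult:
    """Run every stage and (optionally) write artifacts to ``config.out_dir``.

    Deterministic for a fixed config and seed.  Raises with the stage name
    on failure.
    """
    stage = "inputs"
    try:
        if cohort is None and config.bundles_dir is None:
            cohort = generate_cohort(
                config.synthetic or SyntheticParams(seed=config.seed))
        if cohort is not None:
            leads = cohort.leads
            lead_subject = {lid: meta[0]
                            for lid, meta in cohort.lead_meta.items()}
            bundles = {lid: cohort.bundles_for_lead(lid) for lid in leads}
            reviews = cohort.reviews
            tables = cohort.activation_tables
        else:
            leads, lead_subject, bundles, reviews = \
                _load_cohort_from_files(config)
            tables = None

        stage = "activations"
        if tables is None:
            tables = {
                lid: lead_activation_table(
                    bundles[lid], leads[lid], config.vta_params,
                    config.amplitude_grid)
                for lid in sorted(leads)
            }
            logger.info("activations: %d leads x %d configs",
                        len(tables), len(ALL_CONFIGS))
        act_rows = []
        act_map: dict[tuple, float] = {}
        for lid in sorted(tables):
            for pathway, cfgs in tables[lid].items():
                for cfg, profile in cfgs.items():
                    for amp, frac in profile.items():
                        act_map[(lid, cfg, float(amp), pathway)] = frac
                        act_rows.append((lead_subject[lid], lid, cfg,
                                         float(amp), pathway, frac))
        activations = pd.DataFrame(
            act_rows, columns=["subject_id", "lead_id", "config_id",
                               "amplitude_mA", "pathway", "activation"])

        stage = "model fitting"
        cv_results: dict[str, CVResult] = {}
        for pathway in ("HDP", "CST"):
            samples = build_training_samples(reviews, act_map, pathway)
            cv_results[pathway] = loso_cv(samples, config.reg_grid)
            logger.info("%s: %d samples, %d folds, mean accuracy %.3f",
                        pathway, len(samples),
                        len(cv_results[pathway].folds),
                        cv_results[pathway].mean_accuracy)

        stage = "suggestions"
        suggestions: dict[str, dict[str, SuggestionResult]] = {
            s: {} for s in config.strategies}
        lead_thresholds: dict[str, dict[str, ConfigThresholds]] = {}
        for lid in sorted(leads):
            subject = lead_subject[lid]
            try:
                hdp_model = cv_results["HDP"].fold_for_subject(subject).model
                cst_model = cv_results["CST"].fold_for_subject(subject).model
            except KeyError:
                warnings.warn(f"lead {lid}: no held-out fold, skipped")
                continue
            thr = config_thresholds(hdp_model, cst_model,
                                    tables[lid]["HDP"], tables[lid]["CST"])
            lead_thresholds[lid] = thr
            for strategy in config.strategies:
                suggestions[strategy][lid] = suggest_lead(lid, thr, strategy)

        stage = "evaluation"
        rng = np.random.default_rng(config.seed)
        evaluation: dict = {"tasks": {}}
        tasks = []
        for strategy in config.strategies:
            tasks.append((strategy, "best"))
            if strategy == "initial":
                tasks.append((strategy, "worst"))
        for strategy, which in tasks:
            for granularity in ("level", "contact"):
                clin = clinical_labels(reviews, granularity, which)
                sugg = {}
                for lid, res in suggestions[strategy].items():
                    sugg[lid] = (getattr(res, f"{which}_level")
                                 if granularity == "level"
                                 else getattr(res, f"{which}_contact"))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sv, cv_vec, used = label_vectors(sugg, clin, granularity)
                if len(used) == 0 or cv_vec.sum() == 0:
                    continue
                counts = confusion_from_vectors(sv, cv_vec)
                perm = permutation_test(
                    sv, cv_vec, n_perm=config.n_permutations,
                    seed=int(rng.integers(2 ** 31)),
                    mode=config.permutation_mode,
                    block_size=len(LEVEL_CONFIGS) if granularity == "level"
                    else len(CONTACT_CONFIGS))
                evaluation["tasks"][f"{strategy}_{which}_{granularity}"] = {
                    "sensitivity": counts.tp / (counts.tp + counts.fn),
                    "specificity": counts.tn / (counts.tn + counts.fp),
                    "balanced_accuracy": perm.observed_statistic,
                    "p_value": perm.p_value,
                    "n_leads": len(used),
                }

        stage = "threshold errors"
        err_summary: dict = {}
        for kind, attr in (("effect", "effect_threshold"),
                           ("side_effect", "side_effect_threshold")):
            sugg_vals, clin_vals, lids = [], [], []
            for r in reviews:
                if not r.tested or r.lead_id not in lead_thresholds:
                    continue
                model_thr = lead_thresholds[r.lead_id].get(r.config_id)
                if model_thr is None:
                    continue
                sugg_vals.append(getattr(model_thr, attr))
                clin_vals.append(getattr(r, attr))
                lids.append(r.lead_id)
            try:
                err_summary[kind] = threshold_errors(sugg_vals, clin_vals, lids)
            except ValueError:
                err_summary[kind] = None

        result = PipelineResult(
            config=config, activations=activations, cv_results=cv_results,
            suggestions=suggestions, evaluation=evaluation,
            threshold_error_summary=err_summary)
        if config.out_dir:
            _write_artifacts(result)
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc


def _write_artifacts(result: PipelineResult) -> None:
    config = result.config
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": config.seed, "config_hash": config.config_hash()}
    acts = result.activations.copy()
    acts.attrs.update(stamp)
    acts.to_csv(out / "activations.csv", index=False)
    cards = {"_meta": stamp}
    for pathway, cv in result.cv_results.items():
        pooled = cv.pooled_boundary
        cards[pathway] = {
            "mean_accuracy": cv.mean_accuracy,
            "ci95": list(cv.ci95),
            "pooled_boundary": pooled,
            "folds": [f.model.to_card() | {"held_out": f.held_out_subject,
                                           "accuracy": f.accuracy}
                      for f in cv.folds],
        }
    write_report(cards, out / "model_cards.json")
    for strategy, by_lead in result.suggestions.items():
        rows = []
        for lid, res in sorted(by_lead.items()):
            rows.append({
                "lead_id": lid, "strategy": strategy,
                "best_level": res.best_level, "best_contact": res.best_contact,
                "worst_level": res.worst_level,
                "worst_contact": res.worst_contact,
                "excluded_configs": ";".join(res.excluded_configs),
                **stamp,
            })
        pd.DataFrame(rows).to_csv(out / f"suggestions_{strategy}.csv",
                                  index=False)
    write_report({"_meta": stamp, **result.evaluation},
                 out / "evaluation.json")
    err = {
        k: ({kk: vv for kk, vv in v.items() if kk != "per_lead_abs"}
            if v else None)
        for k, v in result.threshold_error_summary.items()
    }
    write_report({"_meta": stamp, **err}, out / "threshold_errors.json")
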