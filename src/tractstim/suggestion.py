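"""Programming suggestions from fitted stimulation models.

For every lead configuration the HDP model suggests an effect threshold
and the CST model a side-effect threshold: the lowest amplitude on the
1-8 mA sweep whose activation is classified "effect".  Three selection
strategies then pick the best (and, for the initial strategy, worst)
level and contact:

* initial  — best by lowest suggested effect threshold (HDP model alone);
             worst by lowest suggested side-effect threshold (CST alone).
* combined — drop configurations whose suggested effect threshold is more
             than 1 mA above the suggested side-effect threshold (side
             effects before full effect), then lowest effect threshold.
* window   — widest therapeutic window (side-effect minus effect
             threshold), censored side-effect thresholds entering the
             arithmetic as 8.5 mA (one grid step past the sweep end).

Ties are broken deterministically: larger therapeutic window, then lower
effect threshold, then the more distal configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .lead_vta import CONTACT_CONFIGS, LEVEL_CONFIGS
from .stim_models import StimulationModel, predict_class

__all__ = [
    "ConfigThresholds",
    "SuggestionResult",
    "SUGGESTION_GRID",
    "CENSOR_SUBSTITUTE_MA",
    "suggest_threshold",
    "config_thresholds",
    "suggest_initial",
    "suggest_combined",
    "suggest_window",
    "suggest_lead",
]

#: Amplitudes swept when suggesting thresholds (the clinical review range).
SUGGESTION_GRID = tuple(round(1.0 + 0.5 * k, 1) for k in range(15))

#: Stand-in for a censored side-effect threshold in window arithmetic:
#: one grid step past the end of the sweep.
CENSOR_SUBSTITUTE_MA = 8.5


@dataclass
class ConfigThresholds:
    """Model-suggested thresholds for one configuration of one lead.

    ``None`` thresholds are censored: the model never predicted the
    (side) effect within the sweep.
    """

    config_id: str
    effect_threshold: float | None
    side_effect_threshold: float | None

    @property
    def window(self) -> float | None:
        """Therapeutic window in mA; None when the effect side is censored."""
        if self.effect_threshold is None:
            return None
        se = (self.side_effect_threshold
              if self.side_effect_threshold is not None
              else CENSOR_SUBSTITUTE_MA)
        return se - self.effect_threshold


@dataclass
class SuggestionResult:
    lead_id: str
    strategy: str
    best_level: str | None
    best_contact: str | None
    worst_level: str | None
    worst_contact: str | None
    thresholds: dict[str, ConfigThresholds]
    excluded_configs: tuple[str, ...] = ()


def suggest_threshold(model: StimulationModel,
                      profile: Mapping[float, float],
                      grid: Sequence[float] = SUGGESTION_GRID) -> float | None:
    """Lowest grid amplitude classified as effect; ``None`` if censored.

    ``profile`` maps amplitude (mA) to activation fraction and must cover
    the grid.
    """
    for amp in grid:
        if amp not in profile:
            raise KeyError(f"activation profile lacks amplitude {amp} mA")
        if predict_class(model, profile[amp])[1] == "effect":
            return float(amp)
    return None


def config_thresholds(hdp_model: StimulationModel,
                      cst_model: StimulationModel,
                      hdp_profiles: Mapping[str, Mapping[float, float]],
                      cst_profiles: Mapping[str, Mapping[float, float]],
                      grid: Sequence[float] = SUGGESTION_GRID,
                      ) -> dict[str, ConfigThresholds]:
    """Suggested effect/side-effect thresholds for every configuration."""
    out: dict[str, ConfigThresholds] = {}
    for cfg in hdp_profiles:
        out[cfg] = ConfigThresholds(
            config_id=cfg,
            effect_threshold=suggest_threshold(hdp_model, hdp_profiles[cfg], grid),
            side_effect_threshold=suggest_threshold(
                cst_model, cst_profiles[cfg], grid),
        )
    return out


def _distal_rank(config_id: str) -> int:
    """Lower = more distal; levels and contacts are numbered tip-first."""
    return int(config_id[1])


def _pick_best(cands: Sequence[ConfigThresholds]) -> str | None:
    """Lowest effect threshold; censored ranks last; deterministic ties."""
    scored = [
        (c.effect_threshold, -(c.window if c.window is not None else -1e9),
         _distal_rank(c.config_id), c.config_id)
        for c in cands if c.effect_threshold is not None
    ]
    if not scored:
        return None
    scored.sort(key=lambda t: (t[0], t[1], t[2]))
    return scored[0][3]


def _pick_worst(cands: Sequence[ConfigThresholds]) -> str | None:
    """Lowest side-effect threshold; ties prefer the narrower window."""
    scored = [
        (c.side_effect_threshold,
         c.window if c.window is not None else 1e9,
         _distal_rank(c.config_id), c.config_id)
        for c in cands if c.side_effect_threshold is not None
    ]
    if not scored:
        return None
    scored.sort(key=lambda t: (t[0], t[1], t[2]))
    return scored[0][3]


def _split(thresholds: Mapping[str, ConfigThresholds]):
    levels = [thresholds[c] for c in LEVEL_CONFIGS if c in thresholds]
    contacts = [thresholds[c] for c in CONTACT_CONFIGS if c in thresholds]
    return levels, contacts


def suggest_initial(thresholds: Mapping[str, ConfigThresholds],
                    which: str = "best") -> dict[str, str | None]:
    """Best via the HDP model or worst via the CST model, independently."""
    levels, contacts = _split(thresholds)
    if which == "best":
        return {"level": _pick_best(levels), "contact": _pick_best(contacts)}
    if which == "worst":
        return {"level": _pick_worst(levels), "contact": _pick_worst(contacts)}
    raise ValueError("which must be 'best' or 'worst'")


def _combined_keep(c: ConfigThresholds) -> bool:
    """Keep iff the effect comes no more than 1 mA after the side effect."""
    if c.effect_threshold is None:
        return False
    if c.side_effect_threshold is None:
        return True
    return c.effect_threshold <= c.side_effect_threshold + 1.0


def suggest_combined(thresholds: Mapping[str, ConfigThresholds],
                     ) -> tuple[dict[str, str | None], tuple[str, ...]]:
    """Best level/contact among configs passing the 1 mA rule.

    Returns the picks plus the excluded config ids.
    """
    levels, contacts = _split(thresholds)
    excluded = tuple(c.config_id for c in [*levels, *contacts]
                     if not _combined_keep(c))
    best = {
        "level": _pick_best([c for c in levels if _combined_keep(c)]),
        "contact": _pick_best([c for c in contacts if _combined_keep(c)]),
    }
    return best, excluded


def _pick_widest(cands: Sequence[ConfigThresholds]) -> str | None:
    scored = [
        (-c.window, c.effect_threshold, _distal_rank(c.config_id), c.config_id)
        for c in cands if c.window is not None
    ]
    if not scored:
        return None
    scored.sort(key=lambda t: (t[0], t[1], t[2]))
    return scored[0][3]


def suggest_window(thresholds: Mapping[str, ConfigThresholds],
                   ) -> dict[str, str | None]:
    """Best level/contact by widest therapeutic window."""
    levels, contacts = _split(thresholds)
    return {"level": _pick_widest(levels), "contact": _pick_widest(contacts)}


def suggest_lead(lead_id: str,
                 thresholds: Mapping[str, ConfigThresholds],
                 strategy: str) -> SuggestionResult:
    """Run one strategy on one lead's suggested thresholds."""
    thresholds = dict(thresholds)
    if strategy == "initial":
        best = suggest_initial(thresholds, "best")
        worst = suggest_initial(thresholds, "worst")
        return SuggestionResult(lead_id, strategy, best["level"],
                                best["contact"], worst["level"],
                                worst["contact"], thresholds)
    if strategy == "combined":
        best, excluded = suggest_combined(thresholds)
        return SuggestionResult(lead_id, strategy, best["level"],
                                best["contact"], None, None, thresholds,
                                excluded)
    if strategy == "window":
        best = suggest_window(thresholds)
        return SuggestionResult(lead_id, strategy, best["level"],
                                best["contact"], None, None, thresholds)
    raise ValueError(f"unknown strategy {strategy!r}")
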