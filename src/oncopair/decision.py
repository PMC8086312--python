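"""Decision-threshold calibration and categorical calls.

A single global score threshold is calibrated by grid search: per
cross-validation repeat, the threshold in [0,1] (step 0.01) maximizing the
macro-averaged F1 over the real (non-Unknown) classes; across repeats, the
most common maximizer above a floor of 0.2.  Given a threshold, each query is
called "correct", "mixed", "none" or "other" by comparing its above-threshold
classes with its nominal annotation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .classify import UNKNOWN, ClassificationProfile, CVResult

__all__ = [
    "ThresholdConfig",
    "CategoryCall",
    "macro_f1",
    "optimize_threshold",
    "assign_category",
    "assign_subtype",
]


@dataclass
class ThresholdConfig:
    grid_min: float = 0.0
    grid_max: float = 1.0
    grid_step: float = 0.01
    floor: float = 0.2
    include_unknown: bool = False

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if not (0 <= self.floor < self.grid_max):
            raise ValueError("floor must lie in [0, grid_max)")

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_max - self.grid_min) / self.grid_step))
        return np.round(self.grid_min + self.grid_step * np.arange(n + 1), 10)


@dataclass(frozen=True)
class CategoryCall:
    sample_id: str
    call: str  # correct | mixed | none | other
    classes_above_threshold: tuple[str, ...]


def macro_f1(
    profile: ClassificationProfile,
    truth: pd.Series,
    threshold: float,
    include_unknown: bool = False,
) -> float:
    """Unweighted mean F1 over classes at a score cutoff.

    A sample is predicted positive for class c iff score_c > threshold
    (strict).  F1_c = 2PR/(P+R), taken as 0 when P+R = 0.  The Unknown
    pseudo-class is excluded from the average unless ``include_unknown``.
    """
    if not (0 <= threshold <= 1):
        raise ValueError("threshold must lie in [0,1]")
    truth = truth.reindex(profile.sample_ids)
    if truth.isna().any():
        raise ValueError("truth labels missing for some profile samples")
    classes = [c for c in profile.classes if include_unknown or c != UNKNOWN]
    scores = profile.scores
    f1s = []
    for c in classes:
        pred = (scores[c] > threshold).to_numpy()
        true = (truth == c).to_numpy()
        tp = int((pred & true).sum())
        fp = int((pred & ~true).sum())
        fn = int((~pred & true).sum())
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        f1s.append(f1)
    return float(np.mean(f1s)) if f1s else 0.0


def _maximizers(profile, truth, cfg: ThresholdConfig) -> np.ndarray:
    grid = cfg.grid()
    vals = np.array([macro_f1(profile, truth, t, cfg.include_unknown) for t in grid])
    return grid[np.abs(vals - vals.max()) <= 1e-12]


def optimize_threshold(
    cv: CVResult,
    cfg: Union[ThresholdConfig, None] = None,
    tie_rule: str = "smallest",
) -> float:
    """Mode over repeats of the macro-F1-maximizing grid threshold.

    With ``tie_rule="smallest"`` each repeat contributes its single smallest
    grid maximizer; repeats whose maximizer does not exceed ``cfg.floor`` are
    discarded, the most common surviving value wins, and mode ties go to the
    smaller threshold.  With ``tie_rule="plateau"`` each repeat contributes
    its whole set of maximizing thresholds — the appropriate reading when the
    F1 curve plateaus, as it does for near-perfect classifiers, where the
    smallest maximizer would sit below the floor in every repeat.
    """
    cfg = cfg or ThresholdConfig()
    if tie_rule not in ("smallest", "plateau"):
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    if not cv.repeats:
        raise ValueError("empty cross-validation result")
    eligible: list[float] = []
    argmins: list[float] = []
    for rep in cv.repeats:
        maxima = _maximizers(rep.profile, rep.truth, cfg)
        argmins.append(float(maxima[0]))
        if tie_rule == "smallest":
            if maxima[0] > cfg.floor:
                eligible.append(float(maxima[0]))
        else:
            eligible.extend(float(t) for t in maxima if t > cfg.floor)
    if not eligible:
        raise ValueError(
            f"no repeat's optimal threshold exceeds the floor of {cfg.floor}; "
            f"per-repeat optima were {sorted(set(argmins))} — inspect the "
            "cross-validation quality before calibrating"
        )
    counts = Counter(eligible)
    top = max(counts.values())
    return min(t for t, c in counts.items() if c == top)


def assign_category(
    row: pd.Series, nominal_label: str, threshold: float
) -> CategoryCall:
    """Call one query against its nominal annotation.

    With S the set of real (non-Unknown) classes scoring strictly above the
    threshold: "correct" when S = {nominal}; "mixed" when nominal is in S
    alongside others; "other" when S is non-empty but excludes nominal;
    "none" when S is empty or the overall top score (Unknown included) lands
    on Unknown — the Unknown-top condition takes precedence.
    """
    classes = [str(c) for c in row.index]
    if nominal_label not in classes:
        raise ValueError(f"nominal label {nominal_label!r} not among classes {classes}")
    above = [c for c in classes if c != UNKNOWN and row[c] > threshold]
    top = str(row.idxmax())
    if not above or top == UNKNOWN:
        call = "none"
    elif above == [nominal_label]:
        call = "correct"
    elif nominal_label in above:
        call = "mixed"
    else:
        call = "other"
    return CategoryCall(
        sample_id=str(row.name), call=call, classes_above_threshold=tuple(above)
    )


def assign_subtype(row: pd.Series, threshold: float) -> Union[list[str], str]:
    """Subtype call for one query: all subtypes scoring above the threshold
    (several -> a mixed subtype call), or "Unknown" when none does or the
    Unknown pseudo-class holds the top score.
    """
    classes = [str(c) for c in row.index]
    above = [c for c in classes if c != UNKNOWN and row[c] > threshold]
    if not above or str(row.idxmax()) == UNKNOWN:
        return UNKNOWN
    return above
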