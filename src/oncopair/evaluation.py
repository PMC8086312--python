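"""Performance metrics and auxiliary formulas.

AUPRC (area under the precision-recall curve, step-function convention —
i.e. non-interpolated precision, identical to average precision) is the
primary metric; a parameter-sweep harness wraps cross-validation over a grid
of (n_top_genes, n_top_pairs).  Two small published formulas are included:
the cosine mapping from an ESTIMATE infiltration score to tumor purity, and
per-year citation-count normalization.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

from .classify import (
    UNKNOWN,
    ClassificationProfile,
    CVResult,
    _as_series,
    cross_validate,
)
from .datamodel import ExpressionMatrix, SampleAnnotation, TrainingConfig

__all__ = [
    "auprc",
    "auprc_per_class",
    "parameter_sweep",
    "estimate_to_purity",
    "normalize_citations",
    "PURITY_OFFSET",
    "PURITY_SLOPE",
]

#: constants of the published ESTIMATE-score -> purity cosine fit
PURITY_OFFSET = 0.6049872018   # radians
PURITY_SLOPE = 0.0001467884    # radians per ESTIMATE-score unit


def auprc(scores: Sequence[float], truth: Sequence[int]) -> float:
    """Area under the precision-recall curve (step-wise, all thresholds).

    ``truth`` holds binary ground-truth labels.  Invariant to strictly
    monotone transforms of the scores.
    """
    truth = np.asarray(truth, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if truth.sum() == 0 or truth.sum() == len(truth):
        raise ValueError("need at least one positive and one negative example")
    return float(average_precision_score(truth, scores))


def auprc_per_class(
    profile: ClassificationProfile,
    truth: pd.Series,
    drop_unknown: bool = True,
) -> pd.Series:
    """One-vs-rest AUPRC per class of a score profile."""
    truth = truth.reindex(profile.sample_ids)
    out = {}
    for cls in profile.classes:
        if drop_unknown and cls == UNKNOWN:
            continue
        y = (truth == cls).astype(int).to_numpy()
        if y.sum() == 0 or y.sum() == len(y):
            out[cls] = np.nan
            continue
        out[cls] = auprc(profile.scores[cls].to_numpy(), y)
    return pd.Series(out)


def parameter_sweep(
    matrix: ExpressionMatrix,
    labels: Union[pd.Series, Sequence[SampleAnnotation]],
    n_grid: Sequence[int],
    m_grid: Sequence[int],
    base_config: TrainingConfig,
    n_repeats: int = 5,
    **cv_kwargs,
) -> pd.DataFrame:
    """Cross-validated mean/SD AUPRC over a grid of (n_top_genes, n_top_pairs).

    Infeasible cells (e.g. more genes requested than available) are recorded
    with the failure reason instead of aborting the sweep.
    """
    if not len(n_grid) or not len(m_grid):
        raise ValueError("empty parameter grid")
    labels = _as_series(labels)
    rows = []
    for n in n_grid:
        for m in m_grid:
            cfg = TrainingConfig(**{**base_config.__dict__,
                                    "n_top_genes": int(n), "n_top_pairs": int(m)})
            try:
                cv = cross_validate(matrix, labels, cfg, n_repeats=n_repeats, **cv_kwargs)
                table = cv.auprc_table(drop_unknown=True)
                rows.append({
                    "n_top_genes": n, "m_top_pairs": m,
                    "mean_auprc": float(table["mean"].mean()),
                    "sd_auprc": float(table["mean"].std()),
                    "min_class_auprc": float(table["mean"].min()),
                    "status": "ok",
                })
            except ValueError as exc:
                warnings.warn(f"grid cell (n={n}, m={m}) skipped: {exc}")
                rows.append({
                    "n_top_genes": n, "m_top_pairs": m,
                    "mean_auprc": np.nan, "sd_auprc": np.nan,
                    "min_class_auprc": np.nan, "status": f"skipped: {exc}",
                })
    return pd.DataFrame(rows)


def estimate_to_purity(estimate_score: float) -> float:
    """Tumor purity from an ESTIMATE stromal/immune score:
    purity = cos(0.6049872018 + 0.0001467884 * score).

    The result is not clipped; a warning is emitted outside [0, 1].
    """
    if not np.isfinite(estimate_score):
        raise ValueError("ESTIMATE score must be finite")
    purity = float(np.cos(PURITY_OFFSET + PURITY_SLOPE * estimate_score))
    if not (0 <= purity <= 1):
        warnings.warn(f"purity {purity:.4f} outside [0,1] for score {estimate_score}")
    return purity


def normalize_citations(citation_count: int, years_since_first: float) -> float:
    """Citation counts normalized per year since first documentation."""
    if citation_count < 0:
        raise ValueError("citation count must be non-negative")
    if years_since_first <= 0:
        raise ValueError("years since first documentation must be positive")
    return citation_count / years_since_first
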