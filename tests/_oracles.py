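"""Independent brute-force reference implementations used as test oracles.

These deliberately share no code with the package: plain loops, scipy.stats
for correlation, explicit threshold enumeration.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import pearsonr


def pearson_or_zero(x, t):
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.std(x) == 0 or np.std(t) == 0:
        return 0.0
    return float(pearsonr(x, t).statistic)


def brute_select_class_genes(scores: dict[str, float], n: int):
    """scores: gene -> r.  Sequential disjoint picks with lexicographic ties."""
    up = sorted(scores, key=lambda g: (-scores[g], g))[:n]
    rest = {g: r for g, r in scores.items() if g not in up}
    down = sorted(rest, key=lambda g: (rest[g], g))[:n]
    rest = {g: r for g, r in rest.items() if g not in down}
    invariant = sorted(rest, key=lambda g: (abs(rest[g]), g))[:n]
    return {"up": up, "down": down, "invariant": invariant}


def brute_select_top_pairs(pair_rows: dict[str, np.ndarray], template: np.ndarray,
                           m: int, gene_cap: int):
    """pair_rows: pair name -> binary vector.  Greedy by |r| with per-gene cap."""
    ranked = sorted(
        pair_rows,
        key=lambda name: (-round(abs(pearson_or_zero(pair_rows[name], template)), 12),
                          name),
    )
    counts: dict[str, int] = {}
    chosen = []
    for name in ranked:
        a, _, b = name.partition("_")
        if counts.get(a, 0) >= gene_cap or counts.get(b, 0) >= gene_cap:
            continue
        chosen.append(name)
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
        if len(chosen) == m:
            break
    return chosen


def brute_macro_f1(scores: np.ndarray, classes: list[str], truth: list[str],
                   threshold: float, skip: str = "Unknown"):
    f1s = []
    for k, c in enumerate(classes):
        if c == skip:
            continue
        tp = fp = fn = 0
        for i, true_label in enumerate(truth):
            pred = scores[i, k] > threshold
            if pred and true_label == c:
                tp += 1
            elif pred:
                fp += 1
            elif true_label == c:
                fn += 1
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * p * r / (p + r) if p + r else 0.0)
    return float(np.mean(f1s))


def brute_auprc(scores, truth):
    """Step-wise AUPRC by explicit enumeration of all score thresholds,
    descending: sum of (recall step) * precision at each step."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    order = np.argsort(-scores, kind="stable")
    n_pos = truth.sum()
    area = 0.0
    tp = fp = 0
    prev_recall = 0.0
    i = 0
    while i < len(scores):
        j = i
        while j < len(scores) and scores[order[j]] == scores[order[i]]:
            tp += truth[order[j]]
            fp += 1 - truth[order[j]]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


def brute_category(scores: dict[str, float], nominal: str, threshold: float):
    """Verbal classification rules, written independently of the package."""
    above = sorted(c for c, v in scores.items() if c != "Unknown" and v > threshold)
    top = max(scores, key=lambda c: scores[c])
    if top == "Unknown" or not above:
        return "none"
    if above == [nominal]:
        return "correct"
    if nominal in above:
        return "mixed"
    return "other"
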