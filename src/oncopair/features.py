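"""Feature engineering: template matching, the gene-pair transform, and the
shuffled "Unknown" pseudo-class.

Template matching scores every gene by the Pearson correlation of its
expression with a 1/0 class-membership indicator.  The per-class top
up/down/invariant genes seed all-vs-all candidate gene pairs; each pair
binarizes to 1 within a sample when its first gene is strictly more expressed
than its second.  The most discriminative pairs (again by template matching,
on the binary features) become the classifier's predictors, with a per-gene
occurrence cap so no single gene dominates a class's pair list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, GenePairFeature

__all__ = [
    "GeneScore",
    "template_correlations",
    "select_class_genes",
    "generate_candidate_pairs",
    "pair_transform",
    "select_top_pairs",
    "sample_random_pairs",
    "make_unknown_profiles",
]


@dataclass(frozen=True)
class GeneScore:
    gene_id: str
    class_label: str
    template_correlation: float


def _template_r(values: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r of ``values`` (features x samples) against a vector.

    Zero-variance rows (or a zero-variance template) score 0 by convention.
    """
    t = template.astype(float)
    tc = t - t.mean()
    tnorm = np.sqrt((tc * tc).sum())
    x = values.astype(float)
    xc = x - x.mean(axis=1, keepdims=True)
    xnorm = np.sqrt((xc * xc).sum(axis=1))
    denom = xnorm * tnorm
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ tc) / denom
    r[~np.isfinite(r)] = 0.0
    if tnorm == 0:
        r[:] = 0.0
    return np.clip(r, -1.0, 1.0)


def template_correlations(
    matrix: ExpressionMatrix, labels: pd.Series, target_class: str
) -> list[GeneScore]:
    """Pearson r of every gene against the 1/0 template of ``target_class``.

    ``labels`` maps sample id -> class label and must cover the matrix's
    samples; both the class and its complement need at least 2 members.
    """
    lab = labels.reindex(matrix.sample_ids)
    if lab.isna().any():
        missing = list(lab.index[lab.isna()])[:5]
        raise ValueError(f"samples without labels: {missing}")
    template = (lab == target_class).to_numpy()
    n_in = int(template.sum())
    if n_in < 2 or (len(template) - n_in) < 2:
        raise ValueError(
            f"class {target_class!r} needs >=2 samples in and out of class "
            f"(has {n_in} in, {len(template) - n_in} out)"
        )
    r = _template_r(matrix.values.to_numpy(), template.astype(float))
    return [
        GeneScore(g, target_class, float(ri))
        for g, ri in zip(matrix.gene_ids, r)
    ]


def select_class_genes(scores: list[GeneScore], n: int) -> dict[str, list[str]]:
    """Pick the n most up-, n most down-regulated and n least differential
    genes by template correlation.  The three lists are disjoint; all
    correlation ties break by gene id, lexicographically.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if len(scores) < 3 * n:
        raise ValueError(f"need >= {3 * n} scored genes, have {len(scores)}")
    by_r_desc = sorted(scores, key=lambda s: (-s.template_correlation, s.gene_id))
    up = [s.gene_id for s in by_r_desc[:n]]
    taken = set(up)
    by_r_asc = sorted(
        (s for s in scores if s.gene_id not in taken),
        key=lambda s: (s.template_correlation, s.gene_id),
    )
    down = [s.gene_id for s in by_r_asc[:n]]
    taken |= set(down)
    by_abs = sorted(
        (s for s in scores if s.gene_id not in taken),
        key=lambda s: (abs(s.template_correlation), s.gene_id),
    )
    invariant = [s.gene_id for s in by_abs[:n]]
    return {"up": up, "down": down, "invariant": invariant}


def generate_candidate_pairs(genes: list[str]) -> list[GenePairFeature]:
    """All unordered gene combinations, once each, in canonical orientation
    (gene_a is the lexicographically smaller id): k genes -> k(k-1)/2 pairs.
    """
    uniq = sorted(set(genes))
    if len(uniq) < 2:
        raise ValueError("need >= 2 distinct genes to form pairs")
    return [GenePairFeature(a, b) for a, b in combinations(uniq, 2)]


def pair_transform(
    matrix: ExpressionMatrix, pairs: list[GenePairFeature]
) -> ExpressionMatrix:
    """Binary pair features: entry 1 iff value(gene_a) > value(gene_b)
    strictly within the sample (ties encode 0).  Rows are pair names.

    The output depends only on within-sample orderings, so any strictly
    increasing per-sample distortion of the values leaves it unchanged.
    """
    needed = sorted({g for p in pairs for g in p.genes()})
    missing = [g for g in needed if g not in matrix.values.index]
    if missing:
        raise KeyError(f"pair genes missing from matrix: {missing[:10]}")
    vals = matrix.values
    a_idx = vals.index.get_indexer([p.gene_a for p in pairs])
    b_idx = vals.index.get_indexer([p.gene_b for p in pairs])
    arr = vals.to_numpy()
    binary = (arr[a_idx, :] > arr[b_idx, :]).astype(np.int8)
    df = pd.DataFrame(binary, index=[p.name for p in pairs], columns=vals.columns)
    return ExpressionMatrix(df, "binary")


def select_top_pairs(
    binary: ExpressionMatrix,
    labels: pd.Series,
    target_class: str,
    m: int,
    gene_cap: int = 3,
) -> list[GenePairFeature]:
    """Greedy selection of the m most discriminative pairs for a class.

    Pairs are ranked by |template Pearson r| (ties by pair name); walking down
    the ranking, a pair is skipped when accepting it would push either of its
    genes past ``gene_cap`` occurrences among the class's accepted pairs.
    """
    if m <= 0:
        raise ValueError("m must be positive")
    if binary.value_kind != "binary":
        raise ValueError("select_top_pairs expects a binary pair matrix")
    scores = template_correlations(binary, labels, target_class)
    # |r| quantized so that mathematically tied pairs rank by name regardless
    # of floating-point evaluation order
    ranked = sorted(
        scores, key=lambda s: (-round(abs(s.template_correlation), 12), s.gene_id)
    )
    counts: dict[str, int] = {}
    chosen: list[GenePairFeature] = []
    for s in ranked:
        pair = GenePairFeature.from_name(s.gene_id)
        if counts.get(pair.gene_a, 0) >= gene_cap or counts.get(pair.gene_b, 0) >= gene_cap:
            continue
        chosen.append(pair)
        counts[pair.gene_a] = counts.get(pair.gene_a, 0) + 1
        counts[pair.gene_b] = counts.get(pair.gene_b, 0) + 1
        if len(chosen) == m:
            break
    if len(chosen) < m:
        warnings.warn(
            f"only {len(chosen)} of {m} requested pairs available for "
            f"{target_class!r} under the per-gene cap of {gene_cap}"
        )
    return chosen


def sample_random_pairs(
    candidates: list[GenePairFeature], k: int, seed: int
) -> list[GenePairFeature]:
    """Baseline mode: k pairs drawn uniformly without replacement from the
    candidate pool, replacing discriminative selection."""
    if k > len(candidates):
        raise ValueError(f"cannot draw {k} pairs from a pool of {len(candidates)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=k, replace=False)
    return [candidates[i] for i in sorted(idx)]


def make_unknown_profiles(
    binary_training: ExpressionMatrix, k: int = 70, seed: int = 0
) -> ExpressionMatrix:
    """Synthesize "Unknown" training profiles by shuffling the binary matrix
    across rows then across columns (an independent permutation per row, then
    per column) and sampling k columns without replacement.

    Shuffling conserves the total number of 1-entries while destroying the
    class structure, so the sampled profiles resemble no reference class.
    """
    if binary_training.value_kind != "binary":
        raise ValueError("make_unknown_profiles expects a binary matrix")
    n_rows, n_cols = binary_training.shape
    if k > n_cols:
        raise ValueError(f"cannot sample {k} profiles from {n_cols} columns")
    rng = np.random.default_rng(seed)
    arr = binary_training.values.to_numpy().copy()
    for i in range(n_rows):
        rng.shuffle(arr[i, :])
    for j in range(n_cols):
        rng.shuffle(arr[:, j])
    cols = rng.choice(n_cols, size=k, replace=False)
    df = pd.DataFrame(
        arr[:, cols],
        index=binary_training.values.index,
        columns=[f"Unknown_{i + 1}" for i in range(k)],
    )
    return ExpressionMatrix(df, "binary")
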