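"""Normalization and harmonization applied before feature engineering.

Count depth is equalized by per-sample downsampling (multinomial by default),
expression is made platform-agnostic by per-sample ascending rank transform,
and cross-species queries are harmonized by one-to-one ortholog mapping plus
gene-space intersection with the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datamodel import ExpressionMatrix, OrthologMap

__all__ = [
    "downsample_counts",
    "rank_transform",
    "intersect_genes",
    "map_orthologs",
    "OrthologReport",
]


def downsample_counts(
    matrix: ExpressionMatrix,
    total: int = 500_000,
    seed: int = 0,
    mode: str = "multinomial",
) -> ExpressionMatrix:
    """Downsample every sample to ``total`` counts.

    ``mode="multinomial"`` draws ``total`` reads per sample with probabilities
    proportional to the observed counts (stochastic but seeded);
    ``mode="scale"`` rescales deterministically to the exact expected values
    (non-integer output).  Samples already below ``total`` pass through
    unchanged with a warning — upsampling would fabricate counts.
    """
    if matrix.value_kind != "counts":
        raise ValueError("downsample_counts requires a counts matrix")
    if mode not in ("multinomial", "scale"):
        raise ValueError(f"unknown mode {mode!r}")
    arr = matrix.values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("negative counts")
    rng = np.random.default_rng(seed)
    out = arr.astype(float).copy()
    colsums = arr.sum(axis=0)
    shallow = [s for s, c in zip(matrix.sample_ids, colsums) if c < total]
    if shallow:
        warnings.warn(
            f"{len(shallow)} samples below {total} total counts left unchanged "
            f"(e.g. {shallow[:3]})"
        )
    for j, csum in enumerate(colsums):
        if csum < total:
            continue
        if mode == "scale":
            out[:, j] = arr[:, j] * (total / csum)
        else:
            p = arr[:, j] / csum
            out[:, j] = rng.multinomial(total, p)
    df = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(df, "counts")


def rank_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-sample ascending ranks: the most lowly expressed gene gets rank 1,
    the most highly expressed gene rank G.  Ties receive the average rank.
    Rank profiles are invariant to any strictly increasing per-sample
    transform of the values — the basis of cross-platform scoring.
    """
    if matrix.value_kind == "binary":
        raise ValueError("rank transform of a binary pair matrix is meaningless")
    arr = matrix.values.to_numpy(dtype=float)
    ranks = rankdata(arr, method="average", axis=0)
    df = pd.DataFrame(ranks, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(df, "rank")


def intersect_genes(
    reference: ExpressionMatrix, query: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to the shared gene set, same ordering in both.

    Order follows the reference's gene order.
    """
    ref_genes = reference.values.index
    shared = [g for g in ref_genes if g in set(query.values.index)]
    if not shared:
        ref_ex = list(map(str, ref_genes[:3]))
        q_ex = list(map(str, query.values.index[:3]))
        raise ValueError(
            "no genes in common between reference and query; "
            f"reference ids look like {ref_ex}, query ids like {q_ex} — "
            "check for symbol vs versioned-identifier mismatch"
        )
    return reference.subset_genes(shared), query.subset_genes(shared)


@dataclass
class OrthologReport:
    n_input_genes: int
    n_mapped: int
    n_unmapped: int
    n_ambiguous_dropped: int


def map_orthologs(
    matrix: ExpressionMatrix, omap: OrthologMap
) -> tuple[ExpressionMatrix, OrthologReport]:
    """Rename genes to their orthologs in the target species.

    Only strict one-to-one map entries are used; genes without such a mapping
    are dropped.  Returns the mapped matrix and a report of what was dropped.
    """
    if not omap.pairs:
        raise ValueError("empty ortholog map")
    filtered = omap.filtered()
    n_ambiguous = len(set(omap.pairs)) - len(filtered.pairs)
    mapping = filtered.as_dict()
    genes = matrix.values.index
    keep = [g for g in genes if g in mapping]
    sub = matrix.values.loc[keep].copy()
    sub.index = [mapping[g] for g in keep]
    if pd.Index(sub.index).has_duplicates:
        raise ValueError("ortholog map produced duplicate target ids")
    report = OrthologReport(
        n_input_genes=len(genes),
        n_mapped=len(keep),
        n_unmapped=len(genes) - len(keep),
        n_ambiguous_dropped=n_ambiguous,
    )
    return ExpressionMatrix(sub, matrix.value_kind), report
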