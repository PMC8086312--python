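"""Core domain types.

The central container is :class:`ExpressionMatrix`, a genes x samples numeric
matrix tagged with the kind of values it holds.  Everything downstream (the
pair transform, the forest, the regulatory-network status metric) consumes and
produces these containers rather than bare arrays, so invariants (unique ids,
finite values, orientation) are checked once, at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "OrthologMap",
    "TrainingConfig",
    "GenePairFeature",
]

#: allowed value kinds for an ExpressionMatrix
VALUE_KINDS = ("counts", "intensity", "rank", "binary")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix.

    Parameters
    ----------
    values
        DataFrame with gene ids as the index and sample ids as columns.
        Values must be finite; counts must be non-negative.
    value_kind
        One of ``counts`` (raw RNA-seq counts), ``intensity`` (any monotone
        scale, e.g. microarray), ``rank`` (per-sample ascending ranks) or
        ``binary`` (gene-pair indicator features; rows are pair names).
    """

    values: pd.DataFrame
    value_kind: str = "counts"

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(
                f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}"
            )
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:10]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:10]}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr.astype(float, copy=False)).all():
            raise ValueError("expression values must be finite")
        if self.value_kind == "counts" and arr.size and (arr < 0).any():
            raise ValueError("counts matrix contains negative values")

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Restrict to ``genes`` (order follows the argument)."""
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:10]}")
        return ExpressionMatrix(self.values.loc[list(genes)].copy(), self.value_kind)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:10]}")
        return ExpressionMatrix(self.values[list(samples)].copy(), self.value_kind)


@dataclass(frozen=True)
class SampleAnnotation:
    """One training/query sample's label record."""

    sample_id: str
    class_label: str
    subtype_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.class_label:
            raise ValueError(f"empty class label for sample {self.sample_id!r}")


def annotations_to_series(annotations: list[SampleAnnotation], subtype: bool = False) -> pd.Series:
    """Collapse a list of annotations to a sample_id -> label Series."""
    ids = [a.sample_id for a in annotations]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in annotations")
    lab = [a.subtype_label if subtype else a.class_label for a in annotations]
    return pd.Series(lab, index=ids, dtype=object)


@dataclass
class OrthologMap:
    """Two-column gene map between species (source -> target).

    ``filtered()`` keeps only strict one-to-one pairs: any source gene mapping
    to several targets, or target hit by several sources, is dropped entirely.
    """

    pairs: list[tuple[str, str]]

    def filtered(self) -> "OrthologMap":
        src_counts: dict[str, int] = {}
        tgt_counts: dict[str, int] = {}
        uniq = list(dict.fromkeys(self.pairs))
        for s, t in uniq:
            src_counts[s] = src_counts.get(s, 0) + 1
            tgt_counts[t] = tgt_counts.get(t, 0) + 1
        kept = [(s, t) for s, t in uniq if src_counts[s] == 1 and tgt_counts[t] == 1]
        return OrthologMap(kept)

    def as_dict(self) -> dict[str, str]:
        m = self.filtered()
        d = dict(m.pairs)
        if len(d) != len(m.pairs):
            raise ValueError("ortholog map still ambiguous after one-to-one filtering")
        return d


@dataclass(frozen=True)
class GenePairFeature:
    """Ordered gene pair; binarizes to 1 when gene_a > gene_b within a sample."""

    gene_a: str
    gene_b: str

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"pair of a gene with itself: {self.gene_a}")

    @property
    def name(self) -> str:
        return f"{self.gene_a}_{self.gene_b}"

    @classmethod
    def from_name(cls, name: str) -> "GenePairFeature":
        a, _, b = name.partition("_")
        if not a or not b:
            raise ValueError(f"unparseable pair name: {name!r}")
        return cls(a, b)

    def genes(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass
class TrainingConfig:
    """Knobs of the classifier training pipeline.

    ``n_top_genes`` (n) is the per-class count of up-, down- and invariant
    genes kept by template matching; ``n_top_pairs`` (m) the per-class count of
    discriminative gene pairs; ``gene_cap`` the maximum appearances of any
    single gene among a class's selected pairs.  ``strat_size`` is the
    per-class bootstrap size used for every tree; ``n_unknown`` the number of
    shuffled profiles forming the "Unknown" pseudo-class; ``downsample_total``
    the per-sample count depth after normalization.
    """

    n_top_genes: int = 30
    n_top_pairs: int = 75
    gene_cap: int = 3
    n_trees: int = 2000
    strat_size: int = 60
    n_unknown: int = 70
    downsample_total: int = 500_000
    seed: int = 0
    random_pairs: bool = False  # baseline mode: uniform pair sampling

    def __post_init__(self) -> None:
        for f_ in ("n_top_genes", "n_top_pairs", "gene_cap", "n_trees",
                   "strat_size", "n_unknown", "downsample_total"):
            v = getattr(self, f_)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"{f_} must be a positive integer, got {v!r}")
        if self.gene_cap > self.n_top_pairs:
            raise ValueError("gene_cap must not exceed n_top_pairs")
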