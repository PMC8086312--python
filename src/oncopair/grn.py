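"""Class-specific regulatory subnetworks and the rank-based GRN-status score.

A mutual-information network is inferred by CLR (context likelihood of
relatedness) from a balanced, depth-normalized subsample of the training
compendium.  Per tumor class, the differentially expressed genes (by template
correlation against the class indicator) seed a subnetwork with up/down
direction labels.  A query sample is scored by how well its per-sample gene
ranks reproduce the class's training rank statistics: deviations in the
"wrong" direction incur a modified Z-score, and the status is the
classifier-importance-weighted mean of (C - Zmod) over subnetwork genes,
normalized against the class-of-interest and worst-class training averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .classify import ClassifierModel, UNKNOWN, _as_series
from .datamodel import ExpressionMatrix, SampleAnnotation
from .features import template_correlations
from .preprocess import downsample_counts, rank_transform

__all__ = [
    "GRNConfig",
    "ClassSubnetwork",
    "GRNModel",
    "build_clr_grn",
    "extract_subnetworks",
    "gene_weights_from_model",
    "modified_zscore",
    "grn_status",
    "normalize_grn_status",
    "build_grn_model",
    "score_grn",
]


@dataclass
class GRNConfig:
    """Settings of GRN construction and status scoring.

    ``samples_per_class`` is the balanced subsample used for network
    inference; ``big_constant`` (C) the offset in the status formula, an
    arbitrary large constant; ``de_correlation_floor`` the |template r|
    cutoff defining a class's differentially expressed seed genes.
    """

    samples_per_class: int = 80
    big_constant: float = 1000.0
    de_correlation_floor: float = 0.3
    downsample_total: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.big_constant <= 0:
            raise ValueError("big_constant must be positive")
        if self.samples_per_class < 2:
            raise ValueError("samples_per_class must be >= 2")


@dataclass
class ClassSubnetwork:
    genes: list[str]
    direction: dict[str, str]            # gene -> "up" | "down"
    mu: dict[str, float]                 # training mean rank per gene
    sigma: dict[str, float]              # training rank SD per gene (> 0)
    weights: dict[str, float]            # classifier-derived gene weight (> 0)
    edges: list[tuple[str, str, float]] = field(default_factory=list)
    avg_interest: Optional[float] = None  # mean raw status, class-of-interest
    avg_min: Optional[float] = None       # mean raw status of the min class
    min_class: Optional[str] = None


@dataclass
class GRNModel:
    subnetworks: dict[str, ClassSubnetwork]
    rank_space_genes: list[str]
    config: GRNConfig


# -----------------------------------------------------------------------------
# network inference
# -----------------------------------------------------------------------------

def _balanced_subsample(
    matrix: ExpressionMatrix, labels: pd.Series, per_class: int, rng
) -> tuple[ExpressionMatrix, pd.Series]:
    chosen: list[str] = []
    for cls in sorted(labels.dropna().unique()):
        ids = np.array(labels.index[labels == cls])
        if len(ids) < per_class:
            warnings.warn(
                f"class {cls!r} has {len(ids)} < {per_class} samples; "
                "subsampling with replacement"
            )
            pick = rng.choice(ids, size=per_class, replace=True)
        else:
            pick = rng.choice(ids, size=per_class, replace=False)
        chosen.extend(pick)
    uniq: list[str] = []
    seen: set[str] = set()
    for s in chosen:  # with-replacement draws can repeat ids; keep one copy
        if s not in seen:
            seen.add(s)
            uniq.append(s)
    return matrix.subset_samples(uniq), labels.loc[uniq]


def _pairwise_mi(ranked: np.ndarray) -> np.ndarray:
    """Pairwise mutual information between genes (rows), in nats.

    Each gene is discretized into ceil(sqrt(n)) equal-width bins over its
    observed range; MI is computed from the empirical joint histogram.
    """
    n_genes, n_samples = ranked.shape
    n_bins = int(np.ceil(np.sqrt(n_samples)))
    codes = np.empty((n_genes, n_samples), dtype=np.int64)
    for i in range(n_genes):
        x = ranked[i]
        lo, hi = x.min(), x.max()
        if hi == lo:
            codes[i] = 0
        else:
            codes[i] = np.minimum(((x - lo) / (hi - lo) * n_bins).astype(int), n_bins - 1)
    # marginal entropies
    h = np.empty(n_genes)
    for i in range(n_genes):
        p = np.bincount(codes[i], minlength=n_bins) / n_samples
        p = p[p > 0]
        h[i] = -(p * np.log(p)).sum()
    mi = np.zeros((n_genes, n_genes))
    for i in range(n_genes):
        ci = codes[i] * n_bins
        for j in range(i + 1, n_genes):
            joint = np.bincount(ci + codes[j], minlength=n_bins * n_bins)
            p = joint[joint > 0] / n_samples
            hij = -(p * np.log(p)).sum()
            mi[i, j] = mi[j, i] = max(h[i] + h[j] - hij, 0.0)
    return mi


def build_clr_grn(
    matrix: ExpressionMatrix,
    labels: Union[pd.Series, Sequence[SampleAnnotation]],
    cfg: Optional[GRNConfig] = None,
) -> pd.DataFrame:
    """Infer a gene-gene CLR network from a balanced training subsample.

    Returns the symmetric, zero-diagonal matrix of CLR edge scores
    sqrt(zi^2 + zj^2), where zi is gene i's MI z-score for the edge against
    its own background MI distribution, clipped at 0.
    """
    cfg = cfg or GRNConfig()
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 genes to build a network")
    labels = _as_series(labels).reindex(matrix.sample_ids)
    rng = np.random.default_rng(cfg.seed)
    sub, _ = _balanced_subsample(matrix, labels, cfg.samples_per_class, rng)
    if sub.value_kind == "counts":
        sub = downsample_counts(sub, total=cfg.downsample_total, seed=cfg.seed)
    ranked = rank_transform(sub)
    mi = _pairwise_mi(ranked.values.to_numpy(dtype=float))

    n = mi.shape[0]
    off = ~np.eye(n, dtype=bool)
    means = np.array([mi[i][off[i]].mean() for i in range(n)])
    sds = np.array([mi[i][off[i]].std() for i in range(n)])
    sds[sds == 0] = np.inf  # degenerate background -> z = 0
    z = np.maximum((mi - means[:, None]) / sds[:, None], 0.0)
    clr = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(clr, 0.0)
    return pd.DataFrame(clr, index=matrix.gene_ids, columns=matrix.gene_ids)


def extract_subnetworks(
    network: pd.DataFrame,
    matrix: ExpressionMatrix,
    labels: Union[pd.Series, Sequence[SampleAnnotation]],
    de_correlation_floor: float = 0.3,
) -> dict[str, dict]:
    """Per-class subnetwork gene sets with direction labels.

    Seeds are the genes whose |template Pearson r| for the class reaches the
    floor; the class subnetwork is the seeds' induced subgraph in the CLR
    network (positive edges among seeds).  Direction is up when r > 0.
    """
    labels = _as_series(labels).reindex(matrix.sample_ids)
    universe = [g for g in network.index if g in set(matrix.gene_ids)]
    sub_matrix = matrix.subset_genes(universe)
    out: dict[str, dict] = {}
    for cls in sorted(labels.dropna().unique()):
        scores = template_correlations(sub_matrix, labels, cls)
        seeds = [s for s in scores if abs(s.template_correlation) >= de_correlation_floor]
        if not seeds:
            warnings.warn(f"class {cls!r} has no genes passing the DE floor; empty subnetwork")
            out[cls] = {"genes": [], "direction": {}, "edges": []}
            continue
        genes = [s.gene_id for s in seeds]
        direction = {
            s.gene_id: ("up" if s.template_correlation > 0 else "down") for s in seeds
        }
        sub_net = network.loc[genes, genes]
        edges = [
            (genes[i], genes[j], float(sub_net.iat[i, j]))
            for i in range(len(genes))
            for j in range(i + 1, len(genes))
            if sub_net.iat[i, j] > 0
        ]
        out[cls] = {"genes": genes, "direction": direction, "edges": edges}
    return out


# -----------------------------------------------------------------------------
# status scoring
# -----------------------------------------------------------------------------

class GeneWeights(dict):
    """gene -> weight mapping; genes outside any pair fall back to the floor."""

    def __init__(self, data: dict, floor: float):
        super().__init__(data)
        self.floor = floor

    def __missing__(self, key):
        return self.floor


def gene_weights_from_model(model: ClassifierModel) -> GeneWeights:
    """Per-gene weights: the summed importances of the classifier pairs a
    gene participates in.  Genes with no positive summed importance receive
    the minimum positive weight observed, so no weight is 0.
    """
    if model.feature_importances is None:
        raise ValueError("classifier model carries no feature importances")
    sums: dict[str, float] = {}
    for pair in model.pairs:
        imp = float(model.feature_importances[pair.name])
        for g in pair.genes():
            sums[g] = sums.get(g, 0.0) + imp
    positive = [v for v in sums.values() if v > 0]
    floor = min(positive) if positive else 1.0
    return GeneWeights({g: (v if v > 0 else floor) for g, v in sums.items()}, floor)


def modified_zscore(query_rank: float, mu: float, sigma: float, direction: str) -> float:
    """Directional deviation of a query gene's rank from training.

    z = (rank - mu) / sigma.  A deviation in the expected direction (z >= 0
    for an up gene, z <= 0 for a down gene) scores 0 — the query gene is at
    least as extreme as training; otherwise the absolute z is returned.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    z = (query_rank - mu) / sigma
    if (z >= 0 and direction == "up") or (z <= 0 and direction == "down"):
        return 0.0
    return abs(z)


def grn_status(
    query_ranks: Union[pd.Series, dict],
    class_label: str,
    grn: GRNModel,
    cfg: Optional[GRNConfig] = None,
) -> float:
    """Raw GRN status of one query sample for one class.

    status = sum_i (C - Zmod_i) w_i / sum_i w_i over the class subnetwork's
    genes present in the query (missing genes dropped with a warning).
    """
    cfg = cfg or grn.config
    if class_label not in grn.subnetworks:
        raise KeyError(f"no subnetwork for class {class_label!r}")
    sub = grn.subnetworks[class_label]
    if not sub.genes:
        raise ValueError(f"class {class_label!r} has an empty subnetwork")
    if isinstance(query_ranks, dict):
        query_ranks = pd.Series(query_ranks)
    present = [g for g in sub.genes if g in query_ranks.index]
    if not present:
        raise ValueError("query covers none of the subnetwork's genes")
    if len(present) < len(sub.genes):
        warnings.warn(
            f"{len(sub.genes) - len(present)} subnetwork genes missing from query; dropped"
        )
    num = 0.0
    den = 0.0
    for g in present:
        zmod = modified_zscore(
            float(query_ranks[g]), sub.mu[g], sub.sigma[g], sub.direction[g]
        )
        w = sub.weights[g]
        num += (cfg.big_constant - zmod) * w
        den += w
    return num / den


def normalize_grn_status(raw: float, class_label: str, grn: GRNModel) -> float:
    """Affine rescaling of a raw status against the training references:
    1 at the class-of-interest training mean, 0 at the minimum class's mean.
    Values outside [0,1] are possible and are not clipped.
    """
    sub = grn.subnetworks[class_label]
    if sub.avg_interest is None or sub.avg_min is None:
        raise ValueError("reference status statistics not stored for this class")
    denom = sub.avg_interest - sub.avg_min
    if denom <= 0:
        raise ValueError(
            f"degenerate status references for {class_label!r} "
            f"(interest {sub.avg_interest}, min {sub.avg_min})"
        )
    return (raw - sub.avg_min) / denom


# -----------------------------------------------------------------------------
# model building and scoring
# -----------------------------------------------------------------------------

def build_grn_model(
    matrix: ExpressionMatrix,
    labels: Union[pd.Series, Sequence[SampleAnnotation]],
    classifier: ClassifierModel,
    cfg: Optional[GRNConfig] = None,
) -> GRNModel:
    """Build the full GRN-status model from a labeled training compendium.

    Pairwise MI is quadratic in genes, so the CLR network is inferred on the
    union of per-class differential seed genes rather than the whole
    transcriptome; rank statistics are learned on the full gene space so
    query ranks stay comparable.
    """
    cfg = cfg or GRNConfig()
    labels = _as_series(labels).reindex(matrix.sample_ids)
    rng = np.random.default_rng(cfg.seed)
    sub_matrix, sub_labels = _balanced_subsample(matrix, labels, cfg.samples_per_class, rng)
    if sub_matrix.value_kind == "counts":
        normalized = downsample_counts(sub_matrix, total=cfg.downsample_total, seed=cfg.seed)
    else:
        normalized = sub_matrix

    # per-class DE seeds define the CLR universe
    classes = sorted(sub_labels.dropna().unique())
    seed_scores: dict[str, list] = {}
    universe: list[str] = []
    seen: set[str] = set()
    for cls in classes:
        scores = template_correlations(normalized, sub_labels, cls)
        keep = [s for s in scores if abs(s.template_correlation) >= cfg.de_correlation_floor]
        seed_scores[cls] = keep
        for s in keep:
            if s.gene_id not in seen:
                seen.add(s.gene_id)
                universe.append(s.gene_id)
    if len(universe) < 2:
        raise ValueError("fewer than 2 genes pass the DE floor; lower de_correlation_floor")

    ranked_universe = rank_transform(normalized).subset_genes(universe)
    mi = _pairwise_mi(ranked_universe.values.to_numpy(dtype=float))
    n = mi.shape[0]
    off = ~np.eye(n, dtype=bool)
    means = np.array([mi[i][off[i]].mean() for i in range(n)])
    sds = np.array([mi[i][off[i]].std() for i in range(n)])
    sds[sds == 0] = np.inf
    z = np.maximum((mi - means[:, None]) / sds[:, None], 0.0)
    clr = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(clr, 0.0)
    network = pd.DataFrame(clr, index=universe, columns=universe)

    weights = gene_weights_from_model(classifier)
    ranked_full = rank_transform(normalized)

    subnetworks: dict[str, ClassSubnetwork] = {}
    for cls in classes:
        seeds = seed_scores[cls]
        if not seeds:
            warnings.warn(f"class {cls!r} has an empty subnetwork")
            continue
        cls_samples = list(sub_labels.index[sub_labels == cls])
        genes, direction, mu, sigma, w = [], {}, {}, {}, {}
        for s in seeds:
            g = s.gene_id
            ranks_g = ranked_full.values.loc[g, cls_samples].to_numpy(dtype=float)
            sd = float(ranks_g.std(ddof=1))
            if sd <= 0:
                continue  # zero-variance gene cannot be z-scored
            genes.append(g)
            direction[g] = "up" if s.template_correlation > 0 else "down"
            mu[g] = float(ranks_g.mean())
            sigma[g] = sd
            w[g] = weights[g]
        sub_net = network.loc[genes, genes]
        edges = [
            (genes[i], genes[j], float(sub_net.iat[i, j]))
            for i in range(len(genes))
            for j in range(i + 1, len(genes))
            if sub_net.iat[i, j] > 0
        ]
        subnetworks[cls] = ClassSubnetwork(
            genes=genes, direction=direction, mu=mu, sigma=sigma, weights=w, edges=edges
        )

    model = GRNModel(
        subnetworks=subnetworks,
        rank_space_genes=list(normalized.gene_ids),
        config=cfg,
    )

    # reference status statistics from the training subsample
    for cls, sub in model.subnetworks.items():
        per_class_mean: dict[str, float] = {}
        for other in classes:
            ids = list(sub_labels.index[sub_labels == other])
            statuses = [
                grn_status(ranked_full.values[s], cls, model, cfg) for s in ids
            ]
            per_class_mean[other] = float(np.mean(statuses))
        sub.avg_interest = per_class_mean[cls]
        sub.min_class = min(per_class_mean, key=lambda c: per_class_mean[c])
        sub.avg_min = per_class_mean[sub.min_class]
    return model


def score_grn(
    grn: GRNModel,
    query: ExpressionMatrix,
    class_label: str,
) -> pd.DataFrame:
    """Raw and normalized GRN status for every query sample.

    Query values are rank-transformed per sample over the genes shared with
    the model's rank space, so any strictly monotone per-sample distortion of
    the query leaves the scores unchanged.
    """
    shared = [g for g in grn.rank_space_genes if g in set(query.gene_ids)]
    if not shared:
        raise ValueError("query shares no genes with the model's rank space")
    if len(shared) < len(grn.rank_space_genes):
        warnings.warn(
            f"query covers {len(shared)}/{len(grn.rank_space_genes)} of the "
            "model's rank-space genes; rank scales may shift"
        )
    ranked = rank_transform(query.subset_genes(shared))
    rows = []
    for s in ranked.sample_ids:
        raw = grn_status(ranked.values[s], class_label, grn)
        rows.append(
            {
                "sample_id": s,
                "raw_status": raw,
                "normalized_status": normalize_grn_status(raw, class_label, grn),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
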