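"""Training and scoring of the multi-class tumor classifier.

The classifier is a random forest over binary gene-pair features.  Every tree
is grown on a balanced per-class bootstrap (``strat_size`` samples drawn with
replacement from each class) so that abundant tumor types cannot dominate the
votes; an "Unknown" pseudo-class trained on shuffled pair profiles catches
queries resembling no reference class.  A query's score for a class is the
fraction of trees voting for it, so each score row is a distribution over the
classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .datamodel import (
    ExpressionMatrix,
    GenePairFeature,
    SampleAnnotation,
    TrainingConfig,
    annotations_to_series,
)
from . import features as feat
from .preprocess import downsample_counts

__all__ = [
    "BalancedRandomForest",
    "ClassificationProfile",
    "ClassifierModel",
    "SubtypeModel",
    "CVRepeat",
    "CVResult",
    "train_general",
    "predict",
    "predict_binary",
    "train_subtype",
    "predict_subtype",
    "cross_validate",
]

UNKNOWN = "Unknown"


def _as_series(labels: Union[pd.Series, Sequence[SampleAnnotation]]) -> pd.Series:
    if isinstance(labels, pd.Series):
        return labels
    return annotations_to_series(list(labels))


# -----------------------------------------------------------------------------
# forest
# -----------------------------------------------------------------------------

class BalancedRandomForest:
    """Random forest with a per-class bootstrap of fixed size per tree.

    Each of ``n_trees`` trees is fit on ``strat_size`` samples drawn with
    replacement from every class (classes smaller than ``strat_size`` are
    oversampled), with sqrt(p) features considered per split.  Scores are
    hard-vote fractions over the ensemble.
    """

    def __init__(self, n_trees: int = 2000, strat_size: int = 60, seed: int = 0):
        self.n_trees = int(n_trees)
        self.strat_size = int(strat_size)
        self.seed = int(seed)
        self.trees_: list[DecisionTreeClassifier] = []
        self.classes_: Optional[np.ndarray] = None
        self.n_features_: Optional[int] = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BalancedRandomForest":
        X = np.asarray(X)
        y = np.asarray(y, dtype=object)
        self.classes_ = np.unique(y)
        self.n_features_ = X.shape[1]
        class_idx = {c: np.flatnonzero(y == c) for c in self.classes_}
        for c, idx in class_idx.items():
            if len(idx) < 2:
                raise ValueError(f"class {c!r} has fewer than 2 samples")
        rng = np.random.default_rng(self.seed)
        tree_seeds = rng.integers(0, 2**31 - 1, size=self.n_trees)
        self.trees_ = []
        for t in range(self.n_trees):
            boot = np.concatenate(
                [rng.choice(class_idx[c], size=self.strat_size, replace=True)
                 for c in self.classes_]
            )
            tree = DecisionTreeClassifier(
                max_features="sqrt", random_state=int(tree_seeds[t])
            )
            tree.fit(X[boot], y[boot])
            self.trees_.append(tree)
        return self

    def vote_fractions(self, X: np.ndarray) -> np.ndarray:
        """samples x classes matrix of vote fractions; rows sum to 1."""
        if not self.trees_:
            raise ValueError("forest is not fitted")
        X = np.asarray(X)
        if X.shape[1] != self.n_features_:
            raise ValueError(
                f"query has {X.shape[1]} features, forest expects {self.n_features_}"
            )
        pos = {c: i for i, c in enumerate(self.classes_)}
        counts = np.zeros((X.shape[0], len(self.classes_)), dtype=np.int64)
        for tree in self.trees_:
            pred = tree.predict(X)
            for i, c in enumerate(pred):
                counts[i, pos[c]] += 1
        return counts / self.n_trees

    def feature_importances(self) -> np.ndarray:
        """Mean impurity importance over trees, renormalized to sum to 1."""
        if not self.trees_:
            raise ValueError("forest is not fitted")
        imp = np.mean([t.feature_importances_ for t in self.trees_], axis=0)
        total = imp.sum()
        return imp / total if total > 0 else imp


# -----------------------------------------------------------------------------
# containers
# -----------------------------------------------------------------------------

@dataclass
class ClassificationProfile:
    """Samples x classes score matrix; each row is a distribution in [0,1]."""

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.scores.to_numpy(dtype=float)
        if arr.size:
            if (arr < -1e-12).any() or (arr > 1 + 1e-12).any():
                raise ValueError("scores outside [0,1]")
            rowsums = arr.sum(axis=1)
            if np.abs(rowsums - 1).max() > 1e-9:
                raise ValueError("score rows must sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.scores.index]

    @property
    def classes(self) -> list[str]:
        return [str(c) for c in self.scores.columns]

    def top_class(self) -> pd.Series:
        return self.scores.idxmax(axis=1)


@dataclass
class ClassifierModel:
    """Trained general classifier bundle."""

    classes: list[str]
    pairs: list[GenePairFeature]
    forest: BalancedRandomForest
    config: TrainingConfig
    class_genes: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    class_pairs: dict[str, list[str]] = field(default_factory=dict)
    threshold: Optional[float] = None
    feature_importances: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.classes.count(UNKNOWN) != 1:
            raise ValueError('"Unknown" must appear exactly once in classes')

    def pair_genes(self) -> list[str]:
        return sorted({g for p in self.pairs for g in p.genes()})


@dataclass
class SubtypeModel:
    """Subtype classifier for one parent tumor type.

    Features are the subtype gene-pair bits concatenated with the general
    classifier's score profile of the sample, so the forest can separate the
    parent type from lookalike classes before splitting subtypes.
    """

    parent_class: str
    general_model: ClassifierModel
    classes: list[str]
    pairs: list[GenePairFeature]
    forest: BalancedRandomForest
    config: TrainingConfig
    threshold: Optional[float] = None

    @property
    def n_features(self) -> int:
        return len(self.pairs) + len(self.general_model.classes)


@dataclass
class CVRepeat:
    profile: ClassificationProfile
    truth: pd.Series          # held-out sample id -> true class (incl. Unknown)
    train_samples: list[str]
    holdout_samples: list[str]
    pair_names: list[str]     # features selected inside this training fold
    seed: int


@dataclass
class CVResult:
    repeats: list[CVRepeat]
    classes: list[str]

    def auprc_table(self, drop_unknown: bool = True) -> pd.DataFrame:
        """Per-class AUPRC mean and SD across repeats."""
        from .evaluation import auprc_per_class

        rows = []
        for rep in self.repeats:
            rows.append(auprc_per_class(rep.profile, rep.truth, drop_unknown=drop_unknown))
        per_rep = pd.DataFrame(rows)
        return pd.DataFrame({"mean": per_rep.mean(axis=0), "sd": per_rep.std(axis=0)})


# -----------------------------------------------------------------------------
# training
# -----------------------------------------------------------------------------

def _select_features(
    normalized: ExpressionMatrix,
    labels: pd.Series,
    config: TrainingConfig,
    classes: list[str],
) -> tuple[list[GenePairFeature], dict, dict]:
    """Per-class gene selection, candidate pair generation and pair selection."""
    all_pairs: list[GenePairFeature] = []
    seen: set[str] = set()
    class_genes: dict[str, dict[str, list[str]]] = {}
    class_pairs: dict[str, list[str]] = {}
    rng = np.random.default_rng(config.seed)
    for cls in classes:
        scores = feat.template_correlations(normalized, labels, cls)
        gene_sets = feat.select_class_genes(scores, config.n_top_genes)
        class_genes[cls] = gene_sets
        pool = gene_sets["up"] + gene_sets["down"] + gene_sets["invariant"]
        candidates = feat.generate_candidate_pairs(pool)
        cand_binary = feat.pair_transform(normalized.subset_genes(sorted(set(pool))), candidates)
        if config.random_pairs:
            chosen = feat.sample_random_pairs(
                candidates, config.n_top_pairs, seed=int(rng.integers(2**31 - 1))
            )
        else:
            chosen = feat.select_top_pairs(
                cand_binary, labels, cls, config.n_top_pairs, config.gene_cap
            )
        class_pairs[cls] = [p.name for p in chosen]
        for p in chosen:
            if p.name not in seen:
                seen.add(p.name)
                all_pairs.append(p)
    return all_pairs, class_genes, class_pairs


def train_general(
    matrix: ExpressionMatrix,
    labels: Union[pd.Series, Sequence[SampleAnnotation]],
    config: TrainingConfig,
) -> ClassifierModel:
    """Train the general classifier.

    Pipeline: per-sample count downsampling, per-class template-matched gene
    selection, candidate pair generation and capped discriminative pair
    selection, pair transform of the training samples, synthesis of
    ``n_unknown`` shuffled "Unknown" profiles, and a balanced-bootstrap
    forest fit on the combined binary matrix.
    """
    labels = _as_series(labels).reindex(matrix.sample_ids)
    if labels.isna().any():
        raise ValueError("all training samples need a class label")
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need >= 2 classes to train")
    for cls in classes:
        if (labels == cls).sum() < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
    if UNKNOWN in classes:
        raise ValueError(f'"{UNKNOWN}" is a reserved class label')

    if matrix.value_kind == "counts":
        normalized = downsample_counts(
            matrix, total=config.downsample_total, seed=config.seed
        )
    else:
        normalized = matrix

    pairs, class_genes, class_pairs = _select_features(normalized, labels, config, classes)

    binary = feat.pair_transform(normalized, pairs)
    unknown = feat.make_unknown_profiles(binary, k=config.n_unknown, seed=config.seed)
    X = np.hstack([binary.values.to_numpy(), unknown.values.to_numpy()]).T
    y = np.concatenate([labels.to_numpy(dtype=object),
                        np.array([UNKNOWN] * config.n_unknown, dtype=object)])

    forest = BalancedRandomForest(
        n_trees=config.n_trees, strat_size=config.strat_size, seed=config.seed
    ).fit(X, y)
    importances = pd.Series(forest.feature_importances(), index=[p.name for p in pairs])

    return ClassifierModel(
        classes=list(forest.classes_),
        pairs=pairs,
        forest=forest,
        config=config,
        class_genes=class_genes,
        class_pairs=class_pairs,
        feature_importances=importances,
    )


# -----------------------------------------------------------------------------
# scoring
# -----------------------------------------------------------------------------

def _query_binary(
    model_pairs: list[GenePairFeature],
    query: ExpressionMatrix,
    allow_missing: bool,
    min_gene_overlap: float,
) -> np.ndarray:
    """Pair-transform a query into the model's feature space (pairs x samples)."""
    needed = sorted({g for p in model_pairs for g in p.genes()})
    have = set(query.values.index)
    missing = [g for g in needed if g not in have]
    coverage = 1 - len(missing) / len(needed)
    if coverage < min_gene_overlap:
        raise ValueError(
            f"query covers only {coverage:.1%} of the {len(needed)} genes used by "
            f"the model's pairs (need >= {min_gene_overlap:.0%}); "
            f"missing e.g. {missing[:10]}"
        )
    if missing and not allow_missing:
        raise ValueError(
            f"{len(missing)} model pair genes missing from query "
            f"(e.g. {missing[:10]}); pass allow_missing=True to encode the "
            "affected pairs as 0"
        )
    if missing:
        warnings.warn(
            f"{len(missing)} pair genes missing from query; affected pairs "
            "encoded as 0"
        )
        miss = set(missing)
        ok_pairs = [p for p in model_pairs if p.gene_a not in miss and p.gene_b not in miss]
        ok_binary = feat.pair_transform(query, ok_pairs).values
        out = np.zeros((len(model_pairs), query.shape[1]), dtype=np.int8)
        pos = {p.name: i for i, p in enumerate(model_pairs)}
        for name, row in zip(ok_binary.index, ok_binary.to_numpy()):
            out[pos[name]] = row
        return out
    return feat.pair_transform(query, model_pairs).values.to_numpy()


def predict(
    model: ClassifierModel,
    query: ExpressionMatrix,
    allow_missing: bool = False,
    min_gene_overlap: float = 0.9,
) -> ClassificationProfile:
    """Score query samples against the reference classes.

    The query is never library-size normalized: the pair transform only looks
    at within-sample orderings, so the scores are invariant to any strictly
    monotone per-sample distortion of the values (platform changes).
    """
    binary = _query_binary(model.pairs, query, allow_missing, min_gene_overlap)
    fractions = model.forest.vote_fractions(binary.T)
    df = pd.DataFrame(fractions, index=query.sample_ids, columns=list(model.forest.classes_))
    return ClassificationProfile(df)


def predict_binary(model: ClassifierModel, binary: ExpressionMatrix) -> ClassificationProfile:
    """Score already pair-transformed profiles (rows = the model's pair names)."""
    if binary.value_kind != "binary":
        raise ValueError("predict_binary expects a binary matrix")
    aligned = binary.values.reindex([p.name for p in model.pairs])
    if aligned.isna().to_numpy().any():
        raise ValueError("binary matrix does not cover the model's pairs")
    fractions = model.forest.vote_fractions(aligned.to_numpy().T)
    df = pd.DataFrame(fractions, index=binary.sample_ids, columns=list(model.forest.classes_))
    return ClassificationProfile(df)


# -----------------------------------------------------------------------------
# subtype classifier
# -----------------------------------------------------------------------------

def train_subtype(
    matrix: ExpressionMatrix,
    subtype_labels: Union[pd.Series, Sequence[SampleAnnotation]],
    general_model: ClassifierModel,
    config: TrainingConfig,
    parent_class: str = "",
) -> SubtypeModel:
    """Train a subtype classifier for one parent tumor type.

    ``subtype_labels`` assigns a subtype (or a normal-tissue label) to the
    parent type's samples; samples of all other classes carry no subtype and
    are relabeled "Unknown".  Features are the subtype pair bits plus the
    general classification profile of each sample.
    """
    if isinstance(subtype_labels, pd.Series):
        sub = subtype_labels.reindex(matrix.sample_ids)
    else:
        sub = annotations_to_series(list(subtype_labels), subtype=True).reindex(matrix.sample_ids)
    labels = sub.where(sub.notna(), UNKNOWN).astype(object)
    subtypes = sorted(c for c in labels.unique() if c != UNKNOWN)
    if len(subtypes) < 2:
        raise ValueError("need >= 2 subtypes to train")
    for s in subtypes:
        if (labels == s).sum() < 2:
            raise ValueError(f"subtype {s!r} has fewer than 2 samples")

    if matrix.value_kind == "counts":
        normalized = downsample_counts(matrix, total=config.downsample_total, seed=config.seed)
    else:
        normalized = matrix

    pairs, _, _ = _select_features(normalized, labels, config, subtypes)
    binary = feat.pair_transform(normalized, pairs)
    general_profile = predict(general_model, matrix)
    X = np.hstack([binary.values.to_numpy().T, general_profile.scores.to_numpy()])
    y = labels.to_numpy(dtype=object)

    forest = BalancedRandomForest(
        n_trees=config.n_trees, strat_size=config.strat_size, seed=config.seed
    ).fit(X, y)
    return SubtypeModel(
        parent_class=parent_class,
        general_model=general_model,
        classes=list(forest.classes_),
        pairs=pairs,
        forest=forest,
        config=config,
    )


def predict_subtype(
    model: SubtypeModel,
    query: ExpressionMatrix,
    allow_missing: bool = False,
    min_gene_overlap: float = 0.9,
) -> ClassificationProfile:
    binary = _query_binary(model.pairs, query, allow_missing, min_gene_overlap)
    general_profile = predict(model.general_model, query, allow_missing, min_gene_overlap)
    X = np.hstack([binary.T, general_profile.scores.to_numpy()])
    fractions = model.forest.vote_fractions(X)
    df = pd.DataFrame(fractions, index=query.sample_ids, columns=list(model.forest.classes_))
    return ClassificationProfile(df)


# -----------------------------------------------------------------------------
# cross-validation
# -----------------------------------------------------------------------------

def cross_validate(
    matrix: ExpressionMatrix,
    labels: Union[pd.Series, Sequence[SampleAnnotation]],
    config: TrainingConfig,
    n_repeats: int = 50,
    train_frac: float = 2 / 3,
    holdout_per_class: Optional[int] = None,
    n_unknown_val: int = 40,
) -> CVResult:
    """Repeated stratified 2/3-1/3 validation with in-fold feature selection.

    Per repeat: a stratified ``train_frac`` split, full re-training (gene and
    pair selection happens inside the training fold, so no leakage), a
    balanced held-out draw of ``holdout_per_class`` samples per class plus
    ``n_unknown_val`` shuffled "Unknown" query profiles, and a stored score
    profile with its truth labels.
    """
    labels = _as_series(labels).reindex(matrix.sample_ids)
    classes = sorted(labels.dropna().unique())
    for cls in classes:
        n_cls = int((labels == cls).sum())
        if int(np.floor(n_cls * train_frac)) < 2 or n_cls - int(np.floor(n_cls * train_frac)) < 1:
            raise ValueError(f"class {cls!r} too small for a {train_frac:.0%} split")
    repeats: list[CVRepeat] = []
    for r in range(n_repeats):
        rep_seed = int(np.random.SeedSequence([config.seed, r]).generate_state(1)[0] % (2**31 - 1))
        rng = np.random.default_rng(rep_seed)
        train_ids: list[str] = []
        test_ids: list[str] = []
        for cls in classes:
            ids = np.array(labels.index[labels == cls])
            rng.shuffle(ids)
            n_train = int(np.floor(len(ids) * train_frac))
            train_ids.extend(ids[:n_train])
            test_ids.extend(ids[n_train:])
        rep_config = TrainingConfig(**{**config.__dict__, "seed": rep_seed})
        model = train_general(matrix.subset_samples(train_ids), labels.loc[train_ids], rep_config)

        # balanced held-out draw
        chosen: list[str] = []
        test_lab = labels.loc[test_ids]
        per_class = holdout_per_class
        if per_class is None:
            per_class = min(int((test_lab == c).sum()) for c in classes)
        for cls in classes:
            ids = np.array(test_lab.index[test_lab == cls])
            take = min(per_class, len(ids))
            chosen.extend(rng.choice(ids, size=take, replace=False))
        holdout = matrix.subset_samples(chosen)
        profile = predict(model, holdout)
        truth = labels.loc[chosen].copy()

        # shuffled Unknown validation queries, built from the held-out binary matrix
        ho_binary = feat.pair_transform(
            downsample_counts(holdout, config.downsample_total, seed=rep_seed)
            if holdout.value_kind == "counts" else holdout,
            model.pairs,
        )
        n_unk = min(n_unknown_val, ho_binary.shape[1])
        unk = feat.make_unknown_profiles(ho_binary, k=n_unk, seed=rep_seed)
        unk_profile = predict_binary(model, unk)
        full_scores = pd.concat([profile.scores, unk_profile.scores])
        full_truth = pd.concat([truth, pd.Series(UNKNOWN, index=unk_profile.sample_ids, dtype=object)])
        repeats.append(
            CVRepeat(
                profile=ClassificationProfile(full_scores),
                truth=full_truth,
                train_samples=list(train_ids),
                holdout_samples=list(full_truth.index),
                pair_names=[p.name for p in model.pairs],
                seed=rep_seed,
            )
        )
    return CVResult(repeats=repeats, classes=classes + [UNKNOWN])
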