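"""Synthetic labeled expression compendia with planted class structure.

The generator draws negative-binomial counts around log-normally distributed
gene baselines and plants, for every class, disjoint blocks of up- and
down-regulated signature genes at a fixed log2 effect.  It emulates exactly
the structure the template-matching/top-pair method assumes: class-specific
monotone shifts of a subset of genes over a noisy count background.  Query
simulators produce cancer-model-like profiles of tunable fidelity (convex
blends with background or with a second class, then NB-resampled) and
per-sample monotone "platform shift" distortions for cross-technology tests.
It deliberately does not emulate real-tumor covariance structure, batch
effects or stromal contamination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, OrthologMap, SampleAnnotation

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "generate_subtyped_cohort",
    "simulate_model_queries",
    "monotone_platform_shift",
    "shuffle_query_columns",
    "make_ortholog_fixture",
]


@dataclass
class CohortSpec:
    """Study conditions of a synthetic compendium.

    Defaults are the reference cohort used throughout the test-bench:
    5 classes x 40 samples, 2000 genes, 30 up + 30 down signature genes per
    class planted at log2 fold change 2, NB dispersion 0.1 (variance
    mu + 0.1 mu^2), gene baselines log-normal around ``baseline_mean``.
    """

    n_classes: int = 5
    samples_per_class: int = 40
    n_genes: int = 2000
    n_signature_up: int = 30
    n_signature_down: int = 30
    log2_effect: float = 2.0
    nb_dispersion: float = 0.1
    baseline_mean: float = 300.0
    baseline_sigma: float = 1.5   # sdlog of the log-normal gene baselines
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2 or self.samples_per_class < 2:
            raise ValueError("need >= 2 classes and >= 2 samples per class")
        total_sig = self.n_classes * (self.n_signature_up + self.n_signature_down)
        if self.n_genes < total_sig:
            raise ValueError(
                f"{self.n_genes} genes cannot hold {total_sig} disjoint signature genes"
            )
        if self.nb_dispersion <= 0 or self.baseline_mean <= 0:
            raise ValueError("dispersion and baseline mean must be positive")

    @property
    def class_names(self) -> list[str]:
        return [f"class{i + 1}" for i in range(self.n_classes)]


@dataclass
class SyntheticCohort:
    matrix: ExpressionMatrix
    annotations: list[SampleAnnotation]
    planted: dict[str, dict[str, list[str]]]   # class -> {"up": [...], "down": [...]}
    mean_profiles: pd.DataFrame = field(repr=False, default=None)  # genes x classes NB means
    spec: CohortSpec = None


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, variance = mean + dispersion * mean^2)."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_cohort(spec: Optional[CohortSpec] = None) -> SyntheticCohort:
    """Draw a labeled counts compendium with planted class signatures.

    Class-c samples have their up-signature genes' NB means multiplied by
    2**log2_effect and their down-signature genes' means divided by it.
    The planted gene lists are returned for recovery experiments.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    genes = [f"g{i + 1:05d}" for i in range(spec.n_genes)]
    baselines = spec.baseline_mean * rng.lognormal(
        mean=-spec.baseline_sigma**2 / 2, sigma=spec.baseline_sigma, size=spec.n_genes
    )

    planted: dict[str, dict[str, list[str]]] = {}
    mean_profiles = {}
    cursor = 0
    effect = 2.0 ** spec.log2_effect
    for cls in spec.class_names:
        up = genes[cursor: cursor + spec.n_signature_up]
        cursor += spec.n_signature_up
        down = genes[cursor: cursor + spec.n_signature_down]
        cursor += spec.n_signature_down
        planted[cls] = {"up": up, "down": down}
        mu = baselines.copy()
        up_idx = [genes.index(g) for g in up]
        dn_idx = [genes.index(g) for g in down]
        mu[up_idx] *= effect
        mu[dn_idx] /= effect
        mean_profiles[cls] = mu

    columns = {}
    annotations = []
    for cls in spec.class_names:
        mu = mean_profiles[cls]
        for k in range(spec.samples_per_class):
            sid = f"{cls}_s{k + 1:03d}"
            columns[sid] = _nb_draw(rng, mu, spec.nb_dispersion)
            annotations.append(SampleAnnotation(sid, cls))
    df = pd.DataFrame(columns, index=genes)
    return SyntheticCohort(
        matrix=ExpressionMatrix(df, "counts"),
        annotations=annotations,
        planted=planted,
        mean_profiles=pd.DataFrame(mean_profiles, index=genes),
        spec=spec,
    )


def generate_subtyped_cohort(
    spec: Optional[CohortSpec] = None,
    parent_class: str = "class1",
    n_subtypes: int = 3,
    n_subtype_up: int = 20,
    n_subtype_down: int = 20,
    subtype_log2_effect: Optional[float] = None,
) -> SyntheticCohort:
    """A cohort whose ``parent_class`` samples split into planted subtypes.

    Subtype signatures occupy gene blocks unused by the class signatures and
    are planted on top of the parent class's mean profile.  Subtype names
    (``<parent>_sub<i>``) appear as extra columns of ``mean_profiles`` and as
    extra entries of ``planted``, so the query simulators work on subtypes
    directly; annotations carry the subtype label for parent samples.
    """
    spec = spec or CohortSpec()
    if parent_class not in spec.class_names:
        raise KeyError(f"unknown parent class {parent_class!r}")
    effect = 2.0 ** (subtype_log2_effect if subtype_log2_effect is not None
                     else spec.log2_effect)
    n_class_sig = spec.n_classes * (spec.n_signature_up + spec.n_signature_down)
    needed = n_class_sig + n_subtypes * (n_subtype_up + n_subtype_down)
    if spec.n_genes < needed:
        raise ValueError(f"{spec.n_genes} genes cannot hold {needed} signature genes")
    base = generate_cohort(spec)
    genes = base.matrix.gene_ids
    rng = np.random.default_rng(spec.seed + 1)

    subtype_names = [f"{parent_class}_sub{i + 1}" for i in range(n_subtypes)]
    cursor = n_class_sig
    parent_mu = base.mean_profiles[parent_class].to_numpy()
    sub_profiles = {}
    for name in subtype_names:
        up = genes[cursor: cursor + n_subtype_up]
        cursor += n_subtype_up
        down = genes[cursor: cursor + n_subtype_down]
        cursor += n_subtype_down
        base.planted[name] = {"up": up, "down": down}
        mu = parent_mu.copy()
        mu[[genes.index(g) for g in up]] *= effect
        mu[[genes.index(g) for g in down]] /= effect
        sub_profiles[name] = mu

    # redraw parent samples from their subtype profiles, round-robin assignment
    values = base.matrix.values.copy()
    annotations = []
    for a in base.annotations:
        if a.class_label != parent_class:
            annotations.append(a)
            continue
        k = int(a.sample_id.rsplit("_s", 1)[1]) - 1
        sub = subtype_names[k % n_subtypes]
        values[a.sample_id] = _nb_draw(rng, sub_profiles[sub], spec.nb_dispersion)
        annotations.append(SampleAnnotation(a.sample_id, a.class_label, sub))

    mean_profiles = base.mean_profiles.copy()
    for name, mu in sub_profiles.items():
        mean_profiles[name] = mu
    return SyntheticCohort(
        matrix=ExpressionMatrix(values, "counts"),
        annotations=annotations,
        planted=base.planted,
        mean_profiles=mean_profiles,
        spec=spec,
    )


def simulate_model_queries(
    cohort: SyntheticCohort,
    class_label: str,
    n_queries: int,
    fidelity: float = 1.0,
    mix_class: Optional[str] = None,
    seed: int = 0,
) -> ExpressionMatrix:
    """Cancer-model-like query profiles of tunable fidelity.

    The NB mean is a convex blend: fidelity * class profile + (1 - fidelity)
    * background (the gene baselines) — or the ``mix_class`` profile when
    given, emulating mixed-identity models.  Fidelity 1 reproduces the
    training class; fidelity 0 is pure background.
    """
    if not (0 <= fidelity <= 1):
        raise ValueError("fidelity must lie in [0,1]")
    if class_label not in cohort.mean_profiles.columns:
        raise KeyError(f"unknown class {class_label!r}")
    rng = np.random.default_rng(seed)
    target = cohort.mean_profiles[class_label].to_numpy()
    if mix_class is not None:
        other = cohort.mean_profiles[mix_class].to_numpy()
    else:
        # background = per-gene median over class profiles, which recovers the
        # unperturbed baseline exactly when a gene is planted in at most one class
        other = np.median(cohort.mean_profiles.to_numpy(), axis=1)
    mu = fidelity * target + (1 - fidelity) * other
    cols = {
        f"query_{class_label}_f{fidelity:g}_{i + 1:03d}":
            _nb_draw(rng, mu, cohort.spec.nb_dispersion)
        for i in range(n_queries)
    }
    return ExpressionMatrix(pd.DataFrame(cols, index=cohort.matrix.gene_ids), "counts")


def monotone_platform_shift(
    matrix: ExpressionMatrix, kind: str = "log", seed: int = 0
) -> ExpressionMatrix:
    """Distort every sample by a random strictly increasing transform.

    ``log``: a*log1p(x); ``power``: (x+1)^gamma - 1 with gamma in [0.4, 2.5];
    ``affine_positive``: a*x + b with a > 0, b >= 0.  Within-sample orderings
    are preserved, so rank- and pair-based features are unchanged — the test
    double for cross-technology (e.g. microarray vs RNA-seq) queries.
    """
    if kind not in ("log", "power", "affine_positive"):
        raise ValueError(f"not a monotone transform family: {kind!r}")
    rng = np.random.default_rng(seed)
    arr = matrix.values.to_numpy(dtype=float)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        if kind == "log":
            a = rng.uniform(0.5, 5.0)
            out[:, j] = a * np.log1p(arr[:, j])
        elif kind == "power":
            gamma = rng.uniform(0.4, 2.5)
            out[:, j] = (arr[:, j] + 1.0) ** gamma - 1.0
        else:
            a = rng.uniform(0.5, 5.0)
            b = rng.uniform(0.0, 10.0)
            out[:, j] = a * arr[:, j] + b
    df = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(df, "intensity")


def shuffle_query_columns(matrix: ExpressionMatrix, seed: int = 0) -> ExpressionMatrix:
    """Permute the genes within every sample independently, destroying gene
    identity while keeping each sample's value distribution — queries that
    should resemble no reference class."""
    rng = np.random.default_rng(seed)
    arr = matrix.values.to_numpy().copy()
    for j in range(arr.shape[1]):
        rng.shuffle(arr[:, j])
    df = pd.DataFrame(
        arr,
        index=matrix.values.index,
        columns=[f"shuffled_{c}" for c in matrix.values.columns],
    )
    return ExpressionMatrix(df, matrix.value_kind)


def make_ortholog_fixture(
    genes: list[str],
    n_mapped: int,
    n_decoys: int = 3,
    source_prefix: str = "mmu_",
    target_prefix: str = "hsa_",
    seed: int = 0,
) -> OrthologMap:
    """One-to-one map over the first ``n_mapped`` genes plus one-to-many decoy
    entries that a correct filter must drop."""
    rng = np.random.default_rng(seed)
    pairs = [(source_prefix + g, target_prefix + g) for g in genes[:n_mapped]]
    decoy_sources = rng.choice(genes[n_mapped:], size=min(n_decoys, len(genes) - n_mapped),
                               replace=False)
    for g in decoy_sources:
        pairs.append((source_prefix + str(g), target_prefix + str(g) + "_A"))
        pairs.append((source_prefix + str(g), target_prefix + str(g) + "_B"))
    return OrthologMap(pairs)
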