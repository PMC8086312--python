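"""Shared fixtures: a fast small cohort for unit tests and the reference
synthetic cohort (5 classes x 40 samples, 2000 genes, 30+30 planted signature
genes per class at log2FC 2, NB dispersion 0.1) for the end-to-end checks.
All fixtures are generated programmatically and seeded."""

import warnings

import pandas as pd
import pytest

import oncopair as op
from oncopair.datamodel import annotations_to_series
from oncopair.synthetic import generate_subtyped_cohort


@pytest.fixture(scope="session")
def small_cohort():
    spec = op.CohortSpec(
        n_classes=4, samples_per_class=20, n_genes=400,
        n_signature_up=15, n_signature_down=15, seed=7,
    )
    return op.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_labels(small_cohort):
    return annotations_to_series(small_cohort.annotations)


@pytest.fixture(scope="session")
def small_config():
    return op.TrainingConfig(
        n_top_genes=15, n_top_pairs=30, n_trees=100,
        strat_size=20, n_unknown=30, seed=7,
    )


@pytest.fixture(scope="session")
def small_model(small_cohort, small_labels, small_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return op.train_general(small_cohort.matrix, small_labels, small_config)


@pytest.fixture(scope="session")
def ref_cohort():
    """The reference study conditions of the synthetic test-bench."""
    return op.generate_cohort(op.CohortSpec(seed=101))


@pytest.fixture(scope="session")
def ref_labels(ref_cohort):
    return annotations_to_series(ref_cohort.annotations)


@pytest.fixture(scope="session")
def ref_config():
    # n_trees scaled down from the 2000-tree default for single-CPU runtimes
    return op.TrainingConfig(n_top_genes=30, n_top_pairs=75, n_trees=500, seed=101)


@pytest.fixture(scope="session")
def ref_model(ref_cohort, ref_labels, ref_config):
    return op.train_general(ref_cohort.matrix, ref_labels, ref_config)


@pytest.fixture(scope="session")
def ref_cv(ref_cohort, ref_labels, ref_config):
    return op.cross_validate(
        ref_cohort.matrix, ref_labels, ref_config,
        n_repeats=3, holdout_per_class=12, n_unknown_val=20,
    )


@pytest.fixture(scope="session")
def subtyped_cohort():
    return generate_subtyped_cohort(op.CohortSpec(seed=31), parent_class="class1")


@pytest.fixture(scope="session")
def ref_grn(ref_cohort, ref_labels, ref_model):
    cfg = op.GRNConfig(samples_per_class=30, seed=101)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return op.build_grn_model(ref_cohort.matrix, ref_labels, ref_model, cfg)
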