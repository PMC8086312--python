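"""Template matching, gene/pair selection, the pair transform and the
shuffled Unknown pseudo-class."""

import numpy as np
import pandas as pd
import pytest

import oncopair as op
from oncopair.datamodel import ExpressionMatrix, GenePairFeature
from oncopair.features import (
    GeneScore,
    generate_candidate_pairs,
    make_unknown_profiles,
    pair_transform,
    select_class_genes,
    select_top_pairs,
    template_correlations,
)
from _oracles import brute_select_class_genes, brute_select_top_pairs, pearson_or_zero


def matrix_from(arr, genes=None, samples=None, kind="intensity"):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), kind)


def labels_for(samples, in_class, cls="T", other="N"):
    return pd.Series([cls if s in in_class else other for s in samples], index=samples)


class TestTemplateCorrelations:
    def test_perfect_template_match_scores_one(self):
        arr = np.array([[10, 10, 0, 0], [3, 3, 3, 3]])
        m = matrix_from(arr)
        lab = labels_for(m.sample_ids, m.sample_ids[:2])
        scores = {s.gene_id: s.template_correlation
                  for s in template_correlations(m, lab, "T")}
        assert scores["g0"] == pytest.approx(1.0)

    def test_constant_gene_scores_zero(self):
        arr = np.array([[5, 5, 5, 5], [1, 2, 3, 4]])
        m = matrix_from(arr)
        lab = labels_for(m.sample_ids, m.sample_ids[:2])
        scores = {s.gene_id: s.template_correlation
                  for s in template_correlations(m, lab, "T")}
        assert scores["g0"] == 0.0

    def test_matches_scipy_pearson(self):
        rng = np.random.default_rng(4)
        arr = rng.normal(size=(12, 40))
        m = matrix_from(arr)
        lab = labels_for(m.sample_ids, m.sample_ids[:15])
        template = np.array([1.0] * 15 + [0.0] * 25)
        for s in template_correlations(m, lab, "T"):
            i = int(s.gene_id[1:])
            assert s.template_correlation == pytest.approx(
                pearson_or_zero(arr[i], template), abs=1e-12
            )

    def test_null_genes_have_small_correlation(self):
        rng = np.random.default_rng(11)
        arr = rng.normal(size=(50, 200))
        m = matrix_from(arr)
        lab = labels_for(m.sample_ids, m.sample_ids[:100])
        rs = [abs(s.template_correlation) for s in template_correlations(m, lab, "T")]
        assert np.quantile(rs, 0.95) < 0.3

    def test_small_class_rejected(self):
        m = matrix_from(np.ones((3, 4)))
        lab = labels_for(m.sample_ids, m.sample_ids[:1])
        with pytest.raises(ValueError, match=">=2"):
            template_correlations(m, lab, "T")


class TestSelectClassGenes:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        scores = {f"g{i:02d}": float(r) for i, r in
                  enumerate(rng.uniform(-1, 1, size=18))}
        got = select_class_genes(
            [GeneScore(g, "T", r) for g, r in scores.items()], n=4
        )
        assert got == brute_select_class_genes(scores, 4)

    def test_explicit_ladder(self):
        rs = [0.9, 0.8, 0.5, 0.2, 0.05, -0.05, -0.2, -0.5, -0.8, -0.9]
        scores = [GeneScore(f"g{i}", "T", r) for i, r in enumerate(rs)]
        got = select_class_genes(scores, n=2)
        assert got["up"] == ["g0", "g1"]
        assert got["down"] == ["g9", "g8"]
        assert set(got["invariant"]) == {"g4", "g5"}

    def test_all_ties_break_lexicographically(self):
        scores = [GeneScore(g, "T", 0.5) for g in ["d", "b", "a", "c", "e", "f"]]
        got = select_class_genes(scores, n=2)
        assert got["up"] == ["a", "b"]
        assert got["down"] == ["c", "d"]
        assert got["invariant"] == ["e", "f"]

    def test_lists_disjoint(self):
        rng = np.random.default_rng(5)
        scores = [GeneScore(f"g{i}", "T", float(r))
                  for i, r in enumerate(rng.uniform(-1, 1, 30))]
        got = select_class_genes(scores, n=10)
        all_genes = got["up"] + got["down"] + got["invariant"]
        assert len(set(all_genes)) == 30

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match=">= 9"):
            select_class_genes([GeneScore("a", "T", 0.1)] * 5, n=3)

    def test_invariant_to_sample_order(self, small_cohort, small_labels):
        m = small_cohort.matrix
        perm = list(np.random.default_rng(0).permutation(m.sample_ids))
        s1 = select_class_genes(
            template_correlations(m, small_labels, "class1"), 10)
        s2 = select_class_genes(
            template_correlations(m.subset_samples(perm), small_labels, "class1"), 10)
        assert s1 == s2


class TestCandidatePairs:
    def test_counts(self):
        assert len(generate_candidate_pairs(["a", "b", "c"])) == 3
        assert len(generate_candidate_pairs([f"g{i:02d}" for i in range(90)])) == 4005

    def test_canonical_orientation_no_self_pairs(self):
        pairs = generate_candidate_pairs(["b", "a", "c"])
        for p in pairs:
            assert p.gene_a < p.gene_b
        assert len({p.name for p in pairs}) == 3


class TestPairTransform:
    def test_encoding_rule(self):
        m = matrix_from([[5], [3]], genes=["g1", "g2"])
        assert pair_transform(m, [GenePairFeature("g1", "g2")]).values.iloc[0, 0] == 1
        assert pair_transform(m, [GenePairFeature("g2", "g1")]).values.iloc[0, 0] == 0

    def test_tie_encodes_zero(self):
        m = matrix_from([[4], [4]], genes=["g1", "g2"])
        assert pair_transform(m, [GenePairFeature("g1", "g2")]).values.iloc[0, 0] == 0

    def test_antisymmetry_on_untied_values(self):
        rng = np.random.default_rng(2)
        arr = rng.permutation(np.arange(100.0)).reshape(10, 10)  # distinct values
        m = matrix_from(arr)
        fwd = pair_transform(m, [GenePairFeature("g0", "g5")]).values.to_numpy()
        rev = pair_transform(m, [GenePairFeature("g5", "g0")]).values.to_numpy()
        assert np.array_equal(fwd, 1 - rev)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(8)
        arr = rng.gamma(2, 30, size=(12, 6))
        pairs = generate_candidate_pairs([f"g{i}" for i in range(12)])
        base = pair_transform(matrix_from(arr), pairs).values.to_numpy()
        for f in (np.log1p, lambda x: x**1.7, lambda x: 2.5 * x + 3):
            out = pair_transform(matrix_from(f(arr)), pairs).values.to_numpy()
            assert np.array_equal(base, out)

    def test_missing_gene_listed(self):
        m = matrix_from([[1]], genes=["g0"])
        with pytest.raises(KeyError, match="gX"):
            pair_transform(m, [GenePairFeature("g0", "gX")])


class TestSelectTopPairs:
    def _binary_with_template_rows(self, seed=0, n_pairs=20, n_samples=30):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(8)]
        names = [p.name for p in generate_candidate_pairs(genes)][:n_pairs]
        arr = rng.integers(0, 2, size=(len(names), n_samples)).astype(np.int8)
        m = ExpressionMatrix(
            pd.DataFrame(arr, index=names,
                         columns=[f"s{j}" for j in range(n_samples)]),
            "binary",
        )
        lab = labels_for(m.sample_ids, m.sample_ids[: n_samples // 2])
        return m, lab

    @pytest.mark.parametrize("seed", [0, 3, 9])
    def test_matches_brute_force_greedy(self, seed):
        m, lab = self._binary_with_template_rows(seed)
        got = [p.name for p in select_top_pairs(m, lab, "T", m=8, gene_cap=3)]
        template = (lab == "T").to_numpy().astype(float)
        rows = {name: m.values.loc[name].to_numpy() for name in m.values.index}
        assert got == brute_select_top_pairs(rows, template, m=8, gene_cap=3)

    def test_per_gene_cap_enforced(self):
        # gene X perfectly discriminative in 5 pairs; cap 3 keeps exactly 3
        samples = [f"s{j}" for j in range(20)]
        lab = labels_for(samples, samples[:10])
        template = (lab == "T").to_numpy().astype(np.int8)
        rows, names = [], []
        for partner in ["a", "b", "c", "d", "e"]:
            names.append(f"X_{partner}")
            rows.append(template)
        rng = np.random.default_rng(1)
        for i in range(6):
            names.append(f"m{i}_n{i}")
            rows.append(rng.integers(0, 2, size=20).astype(np.int8))
        m = ExpressionMatrix(pd.DataFrame(rows, index=names, columns=samples), "binary")
        chosen = select_top_pairs(m, lab, "T", m=8, gene_cap=3)
        x_count = sum("X" in p.genes() for p in chosen)
        assert x_count == 3

    def test_exhaustion_warns_and_returns_short_list(self):
        m, lab = self._binary_with_template_rows(2, n_pairs=5)
        with pytest.warns(UserWarning, match="cap"):
            chosen = select_top_pairs(m, lab, "T", m=50, gene_cap=1)
        assert len(chosen) < 50


class TestUnknownProfiles:
    def test_shuffling_conserves_ones_and_shape(self):
        rng = np.random.default_rng(6)
        arr = (rng.uniform(size=(40, 25)) < 0.4).astype(np.int8)
        m = ExpressionMatrix(
            pd.DataFrame(arr, index=[f"pA{i}_pB{i}" for i in range(40)],
                         columns=[f"s{j}" for j in range(25)]),
            "binary",
        )
        out = make_unknown_profiles(m, k=10, seed=1)
        assert out.shape == (40, 10)
        assert out.values.index.tolist() == m.values.index.tolist()
        full_mean = arr.mean()
        assert abs(out.values.to_numpy().mean() - full_mean) < 0.15

    def test_full_shuffle_conserves_total_ones_exactly(self):
        rng = np.random.default_rng(9)
        arr = (rng.uniform(size=(30, 12)) < 0.4).astype(np.int8)
        m = ExpressionMatrix(
            pd.DataFrame(arr, index=[f"a{i}_b{i}" for i in range(30)],
                         columns=[f"s{j}" for j in range(12)]),
            "binary",
        )
        out = make_unknown_profiles(m, k=12, seed=4)  # keep every shuffled column
        assert out.values.to_numpy().sum() == arr.sum()

    def test_k_larger_than_columns_rejected(self):
        m = ExpressionMatrix(
            pd.DataFrame(np.zeros((3, 4), dtype=np.int8),
                         index=["a_b", "c_d", "e_f"],
                         columns=list("wxyz")), "binary")
        with pytest.raises(ValueError):
            make_unknown_profiles(m, k=5, seed=0)

    def test_shuffling_destroys_class_structure(self, small_model, small_cohort,
                                                small_labels):
        from oncopair.features import pair_transform
        binary = pair_transform(small_cohort.matrix, small_model.pairs)
        shuffled = make_unknown_profiles(binary, k=30, seed=3)
        # correlate each shuffled column against each class's mean binary profile
        arr = shuffled.values.to_numpy().astype(float)
        cors = []
        for cls in sorted(small_labels.unique()):
            proto = binary.values.loc[:, small_labels.index[small_labels == cls]]
            proto = proto.mean(axis=1).to_numpy()
            for j in range(arr.shape[1]):
                cors.append(pearson_or_zero(arr[:, j], proto))
        assert abs(np.mean(cors)) < 0.1
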