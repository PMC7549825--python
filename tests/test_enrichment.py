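import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from setbridge.enrichment import (
    ESParams,
    enrichment_score,
    median_rank_score,
    rank_sample,
    transform,
)
from setbridge.genesets import GeneSet, GeneSetCollection
from setbridge.harmonize import ExpressionMatrix


def naive_es(values, member, alpha):
    """Independent oracle: explicit loops over the cumulative-sum definitions."""
    R = len(values)
    order = sorted(range(R), key=lambda i: (-values[i], i))
    in_order = [bool(member[i]) for i in order]
    r_h = sum(in_order)
    denom_h = sum((i + 1) ** (-alpha) for i in range(R) if in_order[i])
    es, p_h, p_nh = 0.0, 0.0, 0.0
    for r in range(R):
        if in_order[r]:
            p_h += (r + 1) ** (-alpha) / denom_h
        else:
            p_nh += 1.0 / (R - r_h)
        es += p_h - p_nh
    return es


class TestRankSample:
    def test_simple_descending_ranks(self):
        assert rank_sample([5, 1, 3]).ranks.tolist() == [1, 3, 2]

    def test_ties_broken_by_input_order(self):
        assert rank_sample([2, 2, 1]).ranks.tolist() == [1, 2, 3]

    def test_rank_invariance_under_monotone_transform(self, rng):
        v = rng.uniform(1, 100, size=40)
        base = rank_sample(v)
        for f in (np.log2, lambda x: 3 * x + 7, lambda x: x**3):
            assert np.array_equal(rank_sample(f(v)).ranks, base.ranks)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            rank_sample([1.0, np.inf, 2.0])

    @given(st.lists(st.integers(-50, 50), min_size=2, max_size=30))
    @settings(derandomize=True, max_examples=50)
    def test_ranks_are_a_permutation(self, values):
        r = rank_sample(values)
        assert sorted(r.ranks.tolist()) == list(range(1, len(values) + 1))


class TestEnrichmentScore:
    def test_top_gene_singleton_set(self):
        walk = enrichment_score(rank_sample([3.0, 2.0, 1.0]), [True, False, False])
        np.testing.assert_allclose(walk.p_h, [1, 1, 1])
        np.testing.assert_allclose(walk.p_nh, [0, 0.5, 1])
        assert walk.es == pytest.approx(1.5)

    def test_bottom_gene_singleton_set(self):
        walk = enrichment_score(rank_sample([3.0, 2.0, 1.0]), [False, False, True])
        np.testing.assert_allclose(walk.p_h, [0, 0, 1])
        np.testing.assert_allclose(walk.p_nh, [0.5, 1, 1])
        assert walk.es == pytest.approx(-1.5)

    def test_unweighted_interleaved_set(self):
        walk = enrichment_score(
            rank_sample([4.0, 3.0, 2.0, 1.0]), [True, False, True, False], ESParams(alpha=0.0)
        )
        np.testing.assert_allclose(walk.p_h, [0.5, 0.5, 1, 1])
        np.testing.assert_allclose(walk.p_nh, [0, 0.5, 0.5, 1])
        assert walk.es == pytest.approx(1.0)

    @pytest.mark.parametrize("alpha", [0.0, 0.25, 1.0])
    def test_matches_naive_oracle_on_random_configurations(self, alpha, rng):
        for _ in range(200):
            R = int(rng.integers(3, 51))
            r_h = int(rng.integers(1, R))
            member = np.zeros(R, dtype=bool)
            member[rng.choice(R, size=r_h, replace=False)] = True
            values = rng.normal(size=R)
            walk = enrichment_score(rank_sample(values), member, ESParams(alpha=alpha))
            assert walk.es == pytest.approx(naive_es(values, member, alpha), abs=1e-10)

    def test_curves_end_at_one(self, rng):
        values = rng.normal(size=25)
        member = np.zeros(25, dtype=bool)
        member[:7] = True
        walk = enrichment_score(rank_sample(values), member)
        assert walk.p_h[-1] == pytest.approx(1.0, abs=1e-12)
        assert walk.p_nh[-1] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(walk.p_h) >= 0) and np.all(np.diff(walk.p_nh) >= 0)
        assert walk.es == pytest.approx(np.sum(walk.p_h - walk.p_nh))

    def test_random_sets_average_near_zero(self, rng):
        # members scattered uniformly: the two curves track each other.  At
        # alpha=0 the score is linear in member positions, so the mean over
        # uniform draws is zero up to sampling error; the default weighting
        # retains a small positive bias but stays far below the extreme case.
        R, r_h = 100, 10
        values = rng.normal(size=R)
        ranked = rank_sample(values)
        extreme = np.zeros(R, dtype=bool)
        extreme[np.argsort(-values)[:r_h]] = True
        for alpha, ratio in ((0.0, 0.05), (0.25, 0.2)):
            params = ESParams(alpha=alpha)
            extreme_es = enrichment_score(ranked, extreme, params).es
            draws = []
            for _ in range(300):
                member = np.zeros(R, dtype=bool)
                member[rng.choice(R, size=r_h, replace=False)] = True
                draws.append(enrichment_score(ranked, member, params).es)
            assert abs(np.mean(draws)) < ratio * extreme_es

    def test_improving_a_member_rank_never_decreases_unweighted_es(self):
        # exhaustive at R=6: move one member to any better rank, others fixed
        R = 6
        values = np.arange(R, 0, -1, dtype=float)
        ranked = rank_sample(values)
        params = ESParams(alpha=0.0)
        for members in itertools.combinations(range(R), 2):
            base_set = set(members)
            es0 = enrichment_score(ranked, [i in base_set for i in range(R)], params).es
            for m in members:
                for better in range(m):  # lower index = better rank here
                    if better in base_set:
                        continue
                    moved = (base_set - {m}) | {better}
                    es1 = enrichment_score(ranked, [i in moved for i in range(R)], params).es
                    assert es1 >= es0 - 1e-12

    def test_empty_and_full_sets_rejected(self):
        ranked = rank_sample([3.0, 2.0, 1.0])
        with pytest.raises(ValueError, match="empty"):
            enrichment_score(ranked, [False, False, False])
        with pytest.raises(ValueError, match="R - R_H"):
            enrichment_score(ranked, [True, True, True])


class TestMedianRankScore:
    def test_odd_and_even_member_counts(self):
        values = np.arange(6, 0, -1, dtype=float)  # gene i has rank i+1
        ranked = rank_sample(values)
        assert median_rank_score(ranked, [True, False, True, False, True, False]) == 3.0
        assert median_rank_score(ranked, [False, True, False, True, False, False]) == 3.0

    def test_all_genes_median(self):
        ranked = rank_sample([4.0, 3.0, 2.0, 1.0])
        assert median_rank_score(ranked, [True] * 4) == 2.5

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            median_rank_score(rank_sample([2.0, 1.0]), [False, False])


class TestTransform:
    def test_shape_and_axes(self, small_expression, small_collection):
        em = transform(small_expression, small_collection)
        assert em.scores.shape == (3, 6)
        assert em.set_names == small_collection.set_names
        assert em.sample_ids == small_expression.sample_ids

    @pytest.mark.parametrize("method", ["es", "median_rank"])
    def test_monotone_invariance_is_exact(self, small_expression, small_collection, method):
        X = np.abs(small_expression.values) + 1.0
        base = ExpressionMatrix(X, small_expression.gene_ids, small_expression.sample_ids)
        ref = transform(base, small_collection, method=method)
        for f in (np.log2, lambda v: 5 * v + 2, lambda v: v**3):
            other = ExpressionMatrix(f(X), base.gene_ids, base.sample_ids)
            out = transform(other, small_collection, method=method)
            np.testing.assert_array_equal(out.scores, ref.scores)

    def test_equals_per_sample_enrichment_calls(self, small_expression, small_collection):
        em = transform(small_expression, small_collection)
        gene_arr = np.array(small_expression.gene_ids)
        for j in range(small_expression.n_samples):
            ranked = rank_sample(small_expression.values[:, j])
            for k, s in enumerate(small_collection):
                walk = enrichment_score(ranked, np.isin(gene_arr, s.members))
                assert em.scores[k, j] == pytest.approx(walk.es, abs=1e-9)

    def test_median_rank_method_matches_per_sample_calls(self, small_expression, small_collection):
        em = transform(small_expression, small_collection, method="median_rank")
        gene_arr = np.array(small_expression.gene_ids)
        for j in range(small_expression.n_samples):
            ranked = rank_sample(small_expression.values[:, j])
            for k, s in enumerate(small_collection):
                expected = median_rank_score(ranked, np.isin(gene_arr, s.members))
                assert em.scores[k, j] == expected

    def test_unmeasured_sets_dropped_with_provenance(self, small_expression):
        coll = GeneSetCollection(
            "c",
            [GeneSet("ok", ("g0", "g1")), GeneSet("ghost", ("zz1", "zz2"))],
        )
        em = transform(small_expression, coll)
        assert em.set_names == ["ok"]
        assert em.provenance["dropped_sets"] == ["ghost"]
        assert em.provenance["measured_members"] == {"ok": 2}

    def test_all_sets_dropped_is_an_error(self, small_expression):
        coll = GeneSetCollection("c", [GeneSet("ghost", ("zz1",))])
        with pytest.raises(ValueError):
            transform(small_expression, coll)

    def test_tsv_round_trip(self, tmp_path, small_expression, small_collection):
        em = transform(small_expression, small_collection)
        em.to_tsv(tmp_path / "es.tsv")
        from setbridge.enrichment import EnrichmentMatrix

        back = EnrichmentMatrix.from_tsv(tmp_path / "es.tsv")
        assert back.set_names == em.set_names
        np.testing.assert_allclose(back.scores, em.scores)
        assert back.provenance["collection"] == "toy"
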