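import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import canlect as cl
from canlect.features import N_TRIPEPTIDES, TRIPEPTIDES
from canlect.selection import _tie_groups


def tail_oracle(n, N, q):
    """Exhaustive pmf summation in log space, independent of scipy.sf."""
    if n == 0:
        return 1.0
    if q == 0.0:
        return 0.0
    if q == 1.0:
        return 1.0
    total = 0.0
    for m in range(n, N + 1):
        logp = (
            math.lgamma(N + 1) - math.lgamma(m + 1) - math.lgamma(N - m + 1)
            + m * math.log(q) + (N - m) * math.log(1 - q)
        )
        total += math.exp(logp)
    return min(total, 1.0)


class TestTabulate:
    def test_hand_counted_toy(self):
        ds = cl.LabeledDataset(
            records=[cl.ProteinRecord("p", "AAAA"), cl.ProteinRecord("n", "ACDE")],
            labels=np.array([1, 0]),
        )
        t = cl.tabulate_counts(ds)
        assert t.m.tolist() == [2, 2]
        assert t.M == 4
        assert t.q.tolist() == [0.5, 0.5]
        assert t.n[TRIPEPTIDES["AAA"], 0] == 2
        assert t.n[TRIPEPTIDES["ACD"], 1] == 1
        assert t.n[TRIPEPTIDES["CDE"], 1] == 1

    def test_invariants(self, small_enriched):
        ds, _ = small_enriched
        t = cl.tabulate_counts(ds)
        assert np.array_equal(t.N, t.n.sum(axis=1))
        assert t.M == t.m.sum()
        assert t.q.sum() == pytest.approx(1.0)
        # total occurrences = sum of (L - 2) over all sequences
        assert t.M == sum(len(r) - 2 for r in ds.records)

    def test_empty_class_is_error(self):
        ds = cl.LabeledDataset(records=[cl.ProteinRecord("p", "AAAA")],
                               labels=np.array([1]))
        with pytest.raises(cl.EmptyClassError):
            cl.tabulate_counts(ds)


class TestBinomialTail:
    @pytest.mark.parametrize(
        "n, N, q, expected",
        [
            (0, 10, 0.3, 1.0),
            (0, 0, 0.5, 1.0),
            (5, 5, 0.5, 0.03125),
            (8, 10, 0.5, 56 / 1024),
        ],
    )
    def test_known_values(self, n, N, q, expected):
        assert cl.binomial_tail(n, N, q) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n, N, q", [(-1, 5, 0.5), (6, 5, 0.5), (2, 5, 1.5), (2, 5, -0.1)])
    def test_domain_errors(self, n, N, q):
        with pytest.raises(ValueError):
            cl.binomial_tail(n, N, q)

    @given(
        N=st.integers(min_value=1, max_value=400),
        q=st.floats(min_value=0.01, max_value=0.99),
        data=st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_exhaustive_summation(self, N, q, data):
        n = data.draw(st.integers(min_value=0, max_value=N))
        assert cl.binomial_tail(n, N, q) == pytest.approx(
            tail_oracle(n, N, q), abs=1e-10
        )

    def test_monotone_in_n(self):
        for q in (0.2, 0.5, 0.8):
            tails = [cl.binomial_tail(n, 50, q) for n in range(51)]
            assert all(a >= b for a, b in zip(tails, tails[1:]))

    def test_large_N_stable(self):
        p = cl.binomial_tail(500_500, 1_000_000, 0.5)
        assert 0.0 < p < 0.2
        assert np.isfinite(p)


def make_table(entries):
    """Build a ClassCountTable with the given {tripeptide: (n_pos, n_neg)}."""
    n = np.zeros((N_TRIPEPTIDES, 2), dtype=np.int64)
    for trip, (a, b) in entries.items():
        n[TRIPEPTIDES[trip]] = (a, b)
    return cl.ClassCountTable(n=n)


class TestConfidenceLevels:
    def test_all_in_one_class(self):
        # q = 0.5 by symmetric construction; AAA has all 5 occurrences in class 1
        table = make_table({"AAA": (5, 0), "CCC": (0, 5)})
        r = cl.confidence_levels(table)
        i = TRIPEPTIDES["AAA"]
        assert r.cl[i, 0] == pytest.approx(1 - 0.03125)
        assert r.cl_max[i] == pytest.approx(0.96875)
        assert r.dominant_class[i] == 1

    def test_zero_count_gives_zero_cl(self):
        table = make_table({"AAA": (5, 0), "CCC": (0, 5)})
        r = cl.confidence_levels(table)
        assert r.cl[TRIPEPTIDES["AAA"], 1] == 0.0

    def test_symmetric_counts_equal_class_cls(self):
        table = make_table({"AAA": (3, 3), "CCC": (2, 2)})
        r = cl.confidence_levels(table)
        i = TRIPEPTIDES["AAA"]
        assert r.cl[i, 0] == pytest.approx(r.cl[i, 1])

    def test_ties_adjacent_and_lexicographic(self):
        table = make_table({"CCC": (4, 0), "AAA": (4, 0), "DDD": (0, 8)})
        r = cl.confidence_levels(table)
        ranked = r.ranked_features
        ia, ic = ranked.index("AAA"), ranked.index("CCC")
        assert abs(ia - ic) == 1 and ia < ic

    def test_unobserved_excluded(self, small_enriched):
        ds, _ = small_enriched
        r = cl.confidence_levels(cl.tabulate_counts(ds))
        assert len(r.order) + len(r.unobserved) == N_TRIPEPTIDES
        assert np.all(r.table.N[r.order] > 0)
        assert np.all((r.cl_max >= 0) & (r.cl_max <= 1))

    def test_permutation_invariance(self, small_enriched):
        ds, _ = small_enriched
        r1 = cl.confidence_levels(cl.tabulate_counts(ds))
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(ds))
        r2 = cl.confidence_levels(cl.tabulate_counts(ds.subset(perm)))
        assert np.array_equal(r1.order, r2.order)
        assert np.array_equal(r1.cl_max, r2.cl_max)

    def test_export_frame(self, small_enriched):
        ds, _ = small_enriched
        r = cl.confidence_levels(cl.tabulate_counts(ds))
        df = r.to_frame()
        assert list(df.columns) == [
            "tripeptide", "n_pos", "n_neg", "N", "CL_pos", "CL_neg",
            "CL", "dominant_class", "rank",
        ]
        assert df["rank"].tolist() == list(range(1, len(df) + 1))
        assert (df["CL"].to_numpy()[:-1] >= df["CL"].to_numpy()[1:] - 1e-12).all()


class TestFilterByCL:
    def test_threshold_is_strict(self):
        table = make_table({"AAA": (5, 0), "CCC": (0, 5)})
        r = cl.confidence_levels(table)
        assert cl.filter_by_cl(r, 0.9) == ["AAA", "CCC"]
        assert cl.filter_by_cl(r, 0.96875) == []  # strictly greater

    def test_empty_is_valid(self, small_enriched):
        ds, _ = small_enriched
        r = cl.confidence_levels(cl.tabulate_counts(ds))
        assert cl.filter_by_cl(r, 1 - 1e-15) == []

    def test_threshold_domain(self, small_enriched):
        ds, _ = small_enriched
        r = cl.confidence_levels(cl.tabulate_counts(ds))
        with pytest.raises(ValueError):
            cl.filter_by_cl(r, 1.0)

    def test_planted_recovered_at_high_threshold(self, small_enriched):
        ds, spec = small_enriched
        r = cl.confidence_levels(cl.tabulate_counts(ds))
        kept = cl.filter_by_cl(r, 0.9999)
        assert set(spec.planted) <= set(kept)


class TestTieGroups:
    def test_grouping(self):
        assert _tie_groups(np.array([0.9, 0.9, 0.5, 0.3, 0.3, 0.3])) == [2, 1, 3]
        assert _tie_groups(np.array([0.9])) == [1]
        assert _tie_groups(np.array([])) == []


class TestIFS:
    def test_curve_structure_and_recovery(self, small_enriched):
        ds, spec = small_enriched
        ranking = cl.confidence_levels(cl.tabulate_counts(ds))
        res = cl.incremental_feature_selection(
            ds, ranking, folds=5, seed=0, max_size=60
        )
        sizes = res.subset_sizes
        assert all(a < b for a, b in zip(sizes, sizes[1:]))
        assert all(0.0 <= a <= 1.0 for a in res.cv_accuracy)
        assert max(res.cv_accuracy) >= 0.9
        # by the time the subset covers the planted count, accuracy is high
        # and the subset contains every planted tripeptide
        k = next(i for i, s in enumerate(sizes) if s >= len(spec.planted))
        assert res.cv_accuracy[k] >= 0.9
        assert set(spec.planted) <= set(res.chosen_features(sizes[k]))

    def test_argmax_is_first_on_ties(self):
        res = cl.IFSResult(
            subset_sizes=[1, 2, 3, 4], cv_accuracy=[0.5, 0.9, 0.9, 0.8],
            ranked_features=list("abcd"), folds=2, seed=0, svm_c=1.0, svm_g=1.0,
        )
        assert res.argmax_size == 2

    def test_full_walk_ends_at_ranked_count(self, toy_dataset):
        ranking = cl.confidence_levels(cl.tabulate_counts(toy_dataset))
        res = cl.incremental_feature_selection(toy_dataset, ranking, folds=2, seed=1)
        assert res.subset_sizes[-1] == len(ranking.order)

    def test_chosen_size_override(self, small_enriched):
        ds, _ = small_enriched
        ranking = cl.confidence_levels(cl.tabulate_counts(ds))
        res = cl.incremental_feature_selection(ds, ranking, folds=5, seed=0, max_size=30)
        assert res.chosen_features(5) == ranking.ranked_features[:5]

    def test_class_size_precondition(self, toy_dataset):
        ranking = cl.confidence_levels(cl.tabulate_counts(toy_dataset))
        with pytest.raises(ValueError, match="members"):
            cl.incremental_feature_selection(toy_dataset, ranking, folds=7)

    def test_null_data_accuracy_near_chance(self, small_null):
        # Rank on an INDEPENDENT null draw so the evaluated features carry no
        # information about the labels being cross-validated; selecting on the
        # same labels would measure selection bias, not classifier behaviour.
        other = cl.generate_null(
            cl.SimSpec(n_pos=30, n_neg=30, length_range=(100, 100), seed=99)
        )
        ranking = cl.confidence_levels(cl.tabulate_counts(other))
        res = cl.incremental_feature_selection(
            small_null, ranking, folds=5, seed=0, max_size=40
        )
        n = len(small_null)
        se = math.sqrt(0.25 / n)
        assert max(res.cv_accuracy) <= 0.5 + 3 * se

    def test_selection_on_evaluated_labels_is_optimistic(self, small_null):
        # documented hazard of the selection-then-CV protocol: ranking on the
        # same labels inflates the curve well above chance on pure noise
        ranking = cl.confidence_levels(cl.tabulate_counts(small_null))
        res = cl.incremental_feature_selection(
            small_null, ranking, folds=5, seed=0, max_size=40
        )
        assert max(res.cv_accuracy) > 0.7
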