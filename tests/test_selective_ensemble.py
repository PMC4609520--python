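import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import acucoder as ac
from acucoder.exceptions import ConfigurationError
from acucoder.records_io import ClinicalRecord, Dataset, DatasetSchema
from acucoder.selective_ensemble import score_table_rows, vote_tuples
from conftest import FixedTupleLearner

THIRDS = ac.MetricConfig()


def _toy_dataset(y_labels, z_labels):
    schema = DatasetSchema(n_icd10=4, n_basic=2, n_keywords=3, n_acupoints=3,
                           tcm_codes=(0, 1, 2, 3))
    records = []
    for y, z in zip(y_labels, z_labels):
        icd10 = np.zeros(4)
        icd10[y] = 1
        records.append(
            ClinicalRecord(
                icd10=icd10,
                basic_info=np.zeros(2),
                text_features=np.zeros(3),
                acupoints=np.zeros(3),
                tcm_dx=z,
            )
        )
    return Dataset(records, schema)


class TestTupleAccuracy:
    def test_perfect_learner(self):
        ds = _toy_dataset([0, 1, 2], [0, 1, 2])
        h = FixedTupleLearner([0, 1, 2], [0, 1, 2])
        assert ac.tuple_accuracy(h, ds, THIRDS) == pytest.approx(1.0)

    def test_never_correct(self):
        ds = _toy_dataset([0, 1], [0, 1])
        h = FixedTupleLearner([3, 3], [3, 3])
        assert ac.tuple_accuracy(h, ds, THIRDS) == 0.0

    def test_hand_evaluated_mixed_case(self):
        # record 1: full tuple match (1/3 + 1/3 + 1/3); record 2: z only (1/3)
        ds = _toy_dataset([0, 1], [2, 3])
        h = FixedTupleLearner([0, 2], [2, 3])
        assert ac.tuple_accuracy(h, ds, THIRDS) == pytest.approx((1 + 1 / 3) / 2)

    def test_range_bound(self, zero_pool, zero_ds):
        mc = ac.MetricConfig(alpha=0.2, beta=0.5, gamma=0.1)
        for h in zero_pool:
            acc = ac.tuple_accuracy(h, zero_ds, mc)
            assert 0.0 <= acc <= 0.2 + 0.5 + 0.1 + 1e-12

    def test_empty_dataset_rejected(self):
        ds = _toy_dataset([], [])
        with pytest.raises(ConfigurationError):
            ac.tuple_accuracy(FixedTupleLearner([], []), ds, THIRDS)


class TestTupleDiversity:
    def test_identical_to_ensemble_is_zero(self):
        ds = _toy_dataset([0, 1], [0, 1])
        h = FixedTupleLearner([0, 1], [0, 1])
        assert ac.tuple_diversity(h, h, ds) == 0.0

    def test_wrong_everywhere_gates_to_zero(self):
        ds = _toy_dataset([0, 1], [0, 1])
        h = FixedTupleLearner([3, 3], [3, 3])
        ens = FixedTupleLearner([0, 1], [0, 1])
        assert ac.tuple_diversity(h, ens, ds) == 0.0

    def test_hand_evaluated(self):
        # h correct on both records; disagrees with the ensemble in both
        # slots on record 1 and agrees on record 2 -> (2^2 + 0) / 2^2 = 1.0
        ds = _toy_dataset([0, 1], [0, 1])
        h = FixedTupleLearner([0, 1], [0, 1])
        ens = FixedTupleLearner([2, 1], [2, 1])
        assert ac.tuple_diversity(h, ens, ds) == pytest.approx(1.0)

    def test_nonnegative(self, zero_pool, zero_ds):
        X = zero_ds.feature_matrix()
        y, z = vote_tuples(zero_pool, X)
        ens = FixedTupleLearner(y, z)
        for h in zero_pool:
            assert ac.tuple_diversity(h, ens, zero_ds) >= 0.0


class TestMajorityVote:
    def test_identical_learners(self):
        hs = [FixedTupleLearner([2], [1]) for _ in range(3)]
        assert ac.majority_vote(hs, np.zeros(5)) == (2, 1)

    def test_vote_counting(self):
        # y votes (A,A,B) -> A; z votes (u,v,v) -> v
        hs = [
            FixedTupleLearner([0], [5]),
            FixedTupleLearner([0], [7]),
            FixedTupleLearner([1], [7]),
        ]
        assert ac.majority_vote(hs, np.zeros(5)) == (0, 7)

    def test_tie_breaks_to_lowest_index(self):
        hs = [FixedTupleLearner([4], [9]), FixedTupleLearner([2], [3])]
        assert ac.majority_vote(hs, np.zeros(5)) == (2, 3)

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            ac.majority_vote([], np.zeros(5))


def _brute_force_nds(rank_pairs):
    """Oracle: enumerate all dominance pairs, peel fronts, sort by
    (front, sum rank, index)."""
    m = len(rank_pairs)
    dominates = {
        (i, j)
        for i, j in itertools.permutations(range(m), 2)
        if rank_pairs[i][0] <= rank_pairs[j][0]
        and rank_pairs[i][1] <= rank_pairs[j][1]
        and rank_pairs[i] != rank_pairs[j]
    }
    front = {}
    remaining = set(range(m))
    level = 0
    while remaining:
        nondom = {
            j for j in remaining
            if not any((i, j) in dominates for i in remaining if i != j)
        }
        for j in nondom:
            front[j] = level
        remaining -= nondom
        level += 1
    order = sorted(range(m), key=lambda i: (front[i], sum(rank_pairs[i]), i))
    ranks = [0] * m
    for pos, i in enumerate(order, start=1):
        ranks[i] = pos
    return ranks


class TestNdsSort:
    def test_published_six_learner_example(self):
        pairs = [(1, 2), (2, 3), (5, 4), (4, 6), (3, 1), (6, 5)]
        scores = ac.nds_sort(pairs, from_ranks=True)
        by_id = {s.learner_id: s for s in scores}
        assert [by_id[i].nds_rank for i in range(6)] == [1, 3, 4, 5, 2, 6]
        assert [by_id[i].sum_rank for i in range(6)] == [3, 5, 9, 10, 4, 11]

    def test_single_learner(self):
        (s,) = ac.nds_sort([(0.5, 0.1)])
        assert s.nds_rank == 1 and s.acc_rank == 1 and s.div_rank == 1

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            m = int(rng.integers(1, 9))
            acc = rng.permutation(m) + 1
            div = rng.permutation(m) + 1
            pairs = list(zip(acc.tolist(), div.tolist()))
            got = {s.learner_id: s.nds_rank for s in ac.nds_sort(pairs, from_ranks=True)}
            want = _brute_force_nds(pairs)
            assert [got[i] for i in range(m)] == want

    def test_metric_input_assigns_descending_ranks(self):
        scores = ac.nds_sort([(0.9, 0.1), (0.8, 0.3), (0.7, 0.2)])
        by_id = {s.learner_id: s for s in scores}
        assert by_id[0].acc_rank == 1 and by_id[2].acc_rank == 3
        assert by_id[1].div_rank == 1 and by_id[0].div_rank == 3

    def test_ranks_are_permutations(self, zero_pool, zero_ds):
        model = ac.fit_selective_ensemble(zero_pool, zero_ds)
        m = len(zero_pool)
        for attr in ("acc_rank", "div_rank", "nds_rank"):
            assert sorted(getattr(s, attr) for s in model.scores) == list(range(1, m + 1))
        for s in model.scores:
            assert s.sum_rank == s.acc_rank + s.div_rank

    def test_non_finite_rejected(self):
        with pytest.raises(ConfigurationError):
            ac.nds_sort([(np.nan, 1.0)])

    @given(st.integers(0, 500))
    @settings(max_examples=30, deadline=None)
    def test_never_places_dominated_ahead(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 9))
        pairs = [(float(a), float(d)) for a, d in rng.random((m, 2))]
        scores = {s.learner_id: s for s in ac.nds_sort(pairs)}
        for i, j in itertools.permutations(range(m), 2):
            si, sj = scores[i], scores[j]
            if (
                si.acc_rank <= sj.acc_rank
                and si.div_rank <= sj.div_rank
                and (si.acc_rank < sj.acc_rank or si.div_rank < sj.div_rank)
            ):
                assert si.nds_rank < sj.nds_rank

    @given(st.integers(0, 500))
    @settings(max_examples=30, deadline=None)
    def test_duplication_keeps_dominance_among_distinct(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 7))
        pairs = [(float(a), float(d)) for a, d in rng.random((m, 2))]
        dup = pairs + [pairs[int(rng.integers(0, m))]]

        def dominated_set(p):
            scores = {s.learner_id: s for s in ac.nds_sort(p)}
            out = set()
            for i, j in itertools.permutations(range(m), 2):
                si, sj = scores[i], scores[j]
                if si.acc_rank <= sj.acc_rank and si.div_rank <= sj.div_rank:
                    out.add((i, j))
            return out

        assert dominated_set(pairs) == dominated_set(dup)


class TestSelectTop:
    def _scores(self, m):
        return ac.nds_sort([(float(m - i), float(i)) for i in range(m)])

    def test_b_100_selects_all(self):
        assert len(ac.select_top(self._scores(7), ac.SelectionConfig(100))) == 7

    def test_b_20_of_10(self):
        scores = self._scores(10)
        chosen = ac.select_top(scores, ac.SelectionConfig(20))
        by_rank = sorted(scores, key=lambda s: s.nds_rank)
        assert chosen == [by_rank[0].learner_id, by_rank[1].learner_id]

    def test_minimum_one_selected(self):
        assert len(ac.select_top(self._scores(3), ac.SelectionConfig(1))) == 1


class TestFitSelectiveEnsemble:
    def test_identical_perfect_learners(self):
        ds = _toy_dataset([0, 1, 2], [0, 1, 2])
        pool = [FixedTupleLearner([0, 1, 2], [0, 1, 2]) for _ in range(5)]
        model = ac.fit_selective_ensemble(pool, ds)
        assert ac.tuple_accuracy(model, ds, THIRDS) == pytest.approx(1.0)

    def test_zero_noise_holdout_recovery(self, zero_ds, zero_ds_held, zero_pool):
        model = ac.fit_selective_ensemble(zero_pool, zero_ds, sel=ac.SelectionConfig(20))
        y, z = model.predict_tuple(zero_ds_held.feature_matrix())
        assert np.array_equal(y, zero_ds_held.icd10_labels())
        assert np.array_equal(z, zero_ds_held.tcm_labels())

    def test_score_table_export(self, zero_ds, zero_pool):
        model = ac.fit_selective_ensemble(zero_pool, zero_ds)
        rows = score_table_rows(model.scores)
        assert [r["nds_rank"] for r in rows] == list(range(1, len(zero_pool) + 1))
        assert {r["learner"] for r in rows} == set(range(len(zero_pool)))
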