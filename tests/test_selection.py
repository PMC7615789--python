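"""Selection core: main feature, effective/redundant split, budget, quotas."""

import numpy as np
import pytest

from cgufs import (
    GroupAnalysis,
    RelevanceTable,
    classify_group_features,
    group_quotas,
    info_gain,
    rank_and_retain,
    run_cgufs,
    select_main_feature,
    total_budget,
)
from cgufs.info_measures import build_relevance_table
from cgufs.synthetic import SyntheticSpec, make_synthetic


def make_table(ig=None, su=None, pairwise=None, d=None):
    d = d if d is not None else len(ig if ig is not None else su)
    ig = np.zeros(d) if ig is None else np.asarray(ig, dtype=float)
    su = np.zeros(d) if su is None else np.asarray(su, dtype=float)
    table = RelevanceTable(
        su_cluster=su,
        ig_cluster=ig,
        entropy_f=np.ones(d),
        entropy_cluster=1.0,
        codes=np.zeros((2, d), dtype=int),
        cluster_codes=np.zeros(2, dtype=int),
    )
    if pairwise:
        table.pairwise_ig.update({(min(p, q), max(p, q)): v for (p, q), v in pairwise.items()})
    return table


class TestSelectMainFeature:
    def test_singleton(self):
        assert select_main_feature([4], make_table(ig=[0, 0, 0, 0, 0.3])) == 4

    def test_argmax(self):
        table = make_table(ig=[0.9, 0.2, 0.5])
        assert select_main_feature([0, 1, 2], table) == 0
        assert select_main_feature([1, 2], table) == 2

    def test_tie_breaks_to_smaller_index(self):
        table = make_table(ig=[0.5, 0.9, 0.9])
        assert select_main_feature([0, 1, 2], table) == 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            select_main_feature([], make_table(d=3))


class TestClassifyGroupFeatures:
    def test_single_member_group(self):
        eff, red = classify_group_features([2], 2, make_table(d=3))
        assert eff == [] and red == []

    def test_inequality_directions(self):
        # q=1 effective: IG(q,C)=0.6 > IG(main,q)=0.2; q=2 redundant: 0.1 < 0.8
        table = make_table(ig=[0.9, 0.6, 0.1], pairwise={(0, 1): 0.2, (0, 2): 0.8})
        eff, red = classify_group_features([0, 1, 2], 0, table)
        assert eff == [1] and red == [2]

    def test_equality_goes_effective(self):
        table = make_table(ig=[0.5, 0.0], pairwise={(0, 1): 0.0})
        eff, red = classify_group_features([0, 1], 0, table)
        assert eff == [1] and red == []

    def test_exact_copy_is_redundant_by_direct_oracle(self):
        # a feature and its exact copy, both informative about the labels
        rng = np.random.default_rng(0)
        pseudo = rng.integers(0, 2, size=60)
        feat = pseudo * 2.0 + rng.standard_normal(60) * 0.2
        values = np.column_stack([feat, feat.copy()])
        table = build_relevance_table(values, pseudo, bins=5)
        # oracle: evaluate both Markov-blanket inequalities directly
        ig_qc = info_gain(table.codes[:, 1], pseudo)
        ig_pq = info_gain(table.codes[:, 0], table.codes[:, 1])
        assert ig_pq > ig_qc  # the copy is subsumed by the original
        eff, red = classify_group_features([0, 1], 0, table)
        assert red == [1] and eff == []

    def test_main_outside_group_rejected(self):
        with pytest.raises(ValueError):
            classify_group_features([0, 1], 5, make_table(d=6))


class TestTotalBudget:
    @pytest.mark.parametrize(
        "d, beta, expected",
        [(100, 0.1, 10), (10, 0.01, 1), (7, 1.0, 7), (100, 0.999, 99)],
    )
    def test_floor_with_minimum(self, d, beta, expected):
        assert total_budget(d, beta) == expected

    @pytest.mark.parametrize("beta", [0.0, -0.5, 1.5])
    def test_invalid_beta(self, beta):
        with pytest.raises(ValueError):
            total_budget(10, beta)


def make_groups(sizes, su, effective_all=True):
    groups, start = [], 0
    for gid, size in enumerate(sizes):
        members = list(range(start, start + size))
        groups.append(
            GroupAnalysis(
                group_id=gid,
                member_indices=members,
                main_index=members[0],
                effective_indices=members[1:] if effective_all else [],
                redundant_indices=[] if effective_all else members[1:],
            )
        )
        start += size
    return groups, make_table(ig=su, su=su)


class TestGroupQuotas:
    def test_equal_mass_divides_evenly(self):
        groups, table = make_groups([4, 4, 4], [0.5] * 12)
        np.testing.assert_array_equal(group_quotas(groups, table, 6), [2, 2, 2])

    def test_largest_remainder_hand_example(self):
        # SU sums (3, 2, 1), n_new = 10 -> raw (5, 3.33, 1.67) -> (5, 3, 2)
        su = [1.0] * 3 + [1.0] * 2 + [1.0]
        groups, table = make_groups([3, 2, 1], su)
        table.su_cluster = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        quotas = group_quotas(groups, table, 10)
        # caps: retainable counts are 3, 2, 1 -> capped (3, 2, 1)
        np.testing.assert_array_equal(quotas, [3, 2, 1])

    def test_largest_remainder_without_caps(self):
        groups, table = make_groups([6, 6, 6], [0.5] * 18)
        table.su_cluster = np.array([0.5] * 6 + [1 / 3] * 6 + [1 / 6] * 6)
        np.testing.assert_array_equal(group_quotas(groups, table, 10), [5, 3, 2])

    def test_cap_and_redistribution(self):
        # one group holds all SU mass but can only retain 2 features
        groups, table = make_groups([2, 5], [1.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        quotas = group_quotas(groups, table, 5)
        assert quotas[0] == 2
        assert quotas.sum() == 5

    def test_zero_su_falls_back_to_group_sizes(self):
        groups, table = make_groups([6, 3], [0.0] * 9)
        np.testing.assert_array_equal(group_quotas(groups, table, 3), [2, 1])

    def test_sum_is_min_of_budget_and_retainable(self):
        groups, table = make_groups([3, 3], [0.4] * 6)
        assert group_quotas(groups, table, 100).sum() == 6


class TestRankAndRetain:
    def test_quota_one_takes_su_maximal_candidate(self):
        groups, table = make_groups([3, 3], [0.0] * 6)
        table.su_cluster = np.array([0.9, 0.2, 0.5, 0.1, 0.8, 0.3])
        retained = rank_and_retain(groups, np.array([1, 1]), table)
        assert retained == [0, 4]

    def test_saturated_quota_keeps_all_candidates_never_redundant(self):
        groups, table = make_groups([4, 2], [0.5] * 6, effective_all=False)
        retained = rank_and_retain(groups, np.array([4, 2]), table)
        assert retained == [0, 4]  # only mains are retainable

    def test_matches_sort_oracle_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            su = rng.random(8)
            groups, table = make_groups([8], su)
            table.su_cluster = su
            quota = int(rng.integers(1, 9))
            retained = rank_and_retain(groups, np.array([quota]), table)
            main = groups[0].main_index
            oracle = sorted(range(8), key=lambda j: (-su[j], j != main, j))[:quota]
            assert retained == sorted(oracle)


@pytest.fixture(scope="module")
def pipeline_result():
    X, truth = make_synthetic(SyntheticSpec(seed=1))
    return X, truth, run_cgufs(X, beta=0.05, seed=1)


class TestRunCgufs:
    def test_partition_property(self, pipeline_result):
        _, _, res = pipeline_result
        for g in res.groups:
            parts = {g.main_index} | set(g.effective_indices) | set(g.redundant_indices)
            assert parts == set(g.member_indices)
            assert len(g.effective_indices) + len(g.redundant_indices) + 1 == len(g.member_indices)

    def test_budget_contract(self, pipeline_result):
        X, _, res = pipeline_result
        retained = res.retained_indices
        assert len(retained) == len(set(retained))
        assert all(0 <= j < X.n_features for j in retained)
        assert len(retained) <= res.budget.n_new
        retainable = sum(len(g.retainable) for g in res.groups)
        assert len(retained) == min(res.budget.n_new, retainable)

    def test_redundant_never_retained(self, pipeline_result):
        _, _, res = pipeline_result
        redundant = {j for g in res.groups for j in g.redundant_indices}
        assert not (set(res.retained_indices) & redundant)

    def test_deterministic_given_seed(self):
        X, _ = make_synthetic(SyntheticSpec(n=40, c=2, g=2, copies=2, d_noise=14, seed=5))
        r1 = run_cgufs(X, k1=5, k2=5, beta=0.2, seed=7, restarts=5)
        r2 = run_cgufs(X, k1=5, k2=5, beta=0.2, seed=7, restarts=5)
        assert r1.retained_indices == r2.retained_indices
        np.testing.assert_array_equal(r1.pseudo_labels, r2.pseudo_labels)

    def test_absolute_budget_override(self):
        X, _ = make_synthetic(SyntheticSpec(n=40, c=2, g=2, copies=2, d_noise=14, seed=5))
        res = run_cgufs(X, k1=5, k2=5, beta=0.9, n_features=3, seed=7, restarts=5)
        assert res.budget.n_new == 3
        assert len(res.retained_indices) <= 3

    def test_exact_duplicates_at_most_one_retained(self):
        # anti-redundancy: exact duplicate sets collapse to one representative
        rng = np.random.default_rng(4)
        pseudo_signal = np.repeat([0.0, 4.0], 20)
        base = pseudo_signal + rng.standard_normal(40)
        X_vals = np.column_stack(
            [base, base.copy(), base.copy(), rng.standard_normal(40), rng.standard_normal(40)]
        )
        from cgufs import DataMatrix

        res = run_cgufs(DataMatrix(values=X_vals), k1=4, k2=3, beta=0.8, seed=0, restarts=5)
        dup_retained = set(res.retained_indices) & {0, 1, 2}
        assert len(dup_retained) <= 1
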