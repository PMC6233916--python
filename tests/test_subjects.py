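"""Jaccard/Ward participant clustering, k-selection and outcome associations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crdnet import synthetic
from crdnet.cohort_io import BinaryProfile
from crdnet.components import rand_index
from crdnet.subjects import (
    associate_outcomes,
    jaccard_distance,
    odds_ratio_wald,
    select_k_calinski_harabasz,
    ward_cluster,
)

from conftest import make_outcomes


def make_profile(values):
    values = np.asarray(values, dtype=int)
    ids = [f"P{i+1:03d}" for i in range(values.shape[0])]
    comps = [f"cmp{j+1:02d}" for j in range(values.shape[1])]
    return BinaryProfile(pd.DataFrame(values, index=ids, columns=comps))


class TestJaccard:
    def test_identical_profiles(self):
        assert jaccard_distance([1, 0, 1], [1, 0, 1]) == 0.0

    def test_disjoint_supports(self):
        assert jaccard_distance([1, 1, 0, 0], [0, 0, 1, 1]) == 1.0

    def test_counting_example(self):
        assert jaccard_distance([1, 0, 1], [1, 1, 0]) == pytest.approx(2 / 3)

    def test_double_zero_is_an_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            jaccard_distance([0, 0], [0, 0])

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_triangle_inequality(self, data):
        bits = st.lists(st.integers(0, 1), min_size=6, max_size=6)
        a = data.draw(bits.filter(any))
        b = data.draw(bits.filter(any))
        c = data.draw(bits.filter(any))
        dab = jaccard_distance(a, b)
        dbc = jaccard_distance(b, c)
        dac = jaccard_distance(a, c)
        assert dac <= dab + dbc + 1e-12


class TestWardClustering:
    def test_three_distinct_profiles_k3_are_singletons(self):
        b = make_profile([[1, 0, 0], [0, 1, 0], [0, 0, 1]])
        cl = ward_cluster(b, k=3)
        assert len(set(cl.labels)) == 3

    def test_merge_heights_monotone(self, rng):
        values = (rng.random((40, 10)) < 0.3).astype(int)
        values[values.sum(axis=1) == 0, 0] = 1
        cl = ward_cluster(make_profile(values), k=3)
        assert (np.diff(cl.linkage_matrix[:, 2]) >= -1e-10).all()

    def test_labels_invariant_to_participant_order(self, rng):
        b, _ = synthetic.generate_archetype_profiles(n_participants=80, seed=4)
        perm = rng.permutation(80)
        b_perm = BinaryProfile(b.data.iloc[perm])
        cl = ward_cluster(b, k=4)
        cl_perm = ward_cluster(b_perm, k=4)
        restored = pd.Series(cl_perm.labels, index=cl_perm.participant_ids)
        assert rand_index(cl.labels, restored.loc[cl.participant_ids].to_numpy()) == 1.0

    def test_k_out_of_range(self):
        b = make_profile([[1, 0], [0, 1], [1, 1]])
        with pytest.raises(ValueError):
            ward_cluster(b, k=5)


class TestKSelection:
    def test_four_archetypes_select_k4(self):
        b, truth = synthetic.generate_archetype_profiles(n_participants=300, seed=1)
        cl = ward_cluster(b, k_range=(2, 8))
        assert cl.k == 4
        assert select_k_calinski_harabasz(cl) == 4
        assert rand_index(cl.labels, truth) >= 0.9

    def test_two_archetypes_select_k2(self):
        b, _ = synthetic.generate_archetype_profiles(
            n_participants=200, mixing=(0.5, 0.5, 0.0, 0.0), seed=2
        )
        cl = ward_cluster(b, k_range=(2, 6))
        assert cl.k == 2

    def test_trace_starts_at_two(self):
        b, _ = synthetic.generate_archetype_profiles(n_participants=100, seed=3)
        cl = ward_cluster(b, k_range=(2, 5))
        assert min(cl.criterion_trace) == 2

    def test_identical_profiles_degenerate(self):
        b = make_profile(np.ones((10, 4), dtype=int))
        with pytest.raises(ValueError, match="identical"):
            ward_cluster(b)


def chi2_textbook(table):
    """Pearson statistic computed from the definition."""
    table = np.asarray(table, float)
    total = table.sum()
    expected = np.outer(table.sum(1), table.sum(0)) / total
    return ((table - expected) ** 2 / expected).sum()


def kruskal_textbook(groups):
    """H statistic from the rank-sum definition with tie correction."""
    from scipy.stats import rankdata

    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    ties = ((counts**3 - counts).sum()) / (n**3 - n)
    return h / (1.0 - ties) if ties < 1 else h


class TestAssociations:
    def _clustered_cohort(self, labels, asthma, lung=None):
        labels = np.asarray(labels)
        n = len(labels)
        values = np.zeros((n, 3), dtype=int)
        values[np.arange(n), (labels - 1) % 3] = 1
        b = make_profile(values)
        cl = ward_cluster(b, k=len(np.unique(labels)))
        # overwrite with the intended labels: association layer only needs them
        cl.labels = labels
        out = make_outcomes(asthma, participant_ids=b.participant_ids,
                            **({"fev1": lung} if lung is not None else {}))
        return cl, out

    def test_odds_ratio_direct_formula(self):
        or_, lo, hi, p, corrected = odds_ratio_wald(10, 10, 5, 20)
        assert or_ == pytest.approx(4.0)
        assert lo < 4.0 < hi
        assert not corrected

    def test_symmetric_table_or_one(self):
        or_, lo, hi, _, _ = odds_ratio_wald(7, 7, 7, 7)
        assert or_ == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_zero_cell_triggers_continuity_correction(self):
        or_, _, _, _, corrected = odds_ratio_wald(0, 10, 5, 5)
        assert corrected
        assert np.isfinite(or_)

    def test_chi2_matches_textbook_formula(self):
        labels = np.repeat([1, 2, 3], [30, 30, 40])
        asthma = np.r_[np.repeat(1, 18), np.repeat(0, 12),
                       np.repeat(1, 6), np.repeat(0, 24),
                       np.repeat(1, 10), np.repeat(0, 30)]
        cl, out = self._clustered_cohort(labels, asthma)
        report = associate_outcomes(cl, out)
        table = np.array([[18, 12], [6, 24], [10, 30]])
        assert report.chi2["asthma"]["statistic"] == pytest.approx(
            chi2_textbook(table), abs=1e-10
        )

    def test_kruskal_matches_textbook_formula(self, rng):
        labels = np.repeat([1, 2, 3], 25)
        asthma = rng.integers(0, 2, size=75)
        lung = np.r_[rng.normal(0, 1, 25), rng.normal(0.5, 1, 25), rng.normal(1, 1, 25)]
        cl, out = self._clustered_cohort(labels, asthma, lung=lung)
        report = associate_outcomes(cl, out)
        expected = kruskal_textbook([lung[:25], lung[25:50], lung[50:]])
        assert report.kruskal_wallis["fev1"]["statistic"] == pytest.approx(
            expected, abs=1e-10
        )

    def test_or_reference_modes(self):
        labels = np.repeat([1, 2], [40, 40])
        asthma = np.r_[np.repeat(1, 20), np.repeat(0, 20),
                       np.repeat(1, 8), np.repeat(0, 32)]
        cl, out = self._clustered_cohort(labels, asthma)
        rest = associate_outcomes(cl, out, reference="rest")
        vs_c2 = associate_outcomes(cl, out, reference="2")
        or_rest = rest.odds_ratios["asthma"][0].odds_ratio
        or_vs2 = vs_c2.odds_ratios["asthma"][0].odds_ratio
        # two clusters: cluster 1 vs rest is the same 2x2 table as vs cluster 2
        assert or_rest == pytest.approx(or_vs2) == pytest.approx((20 * 32) / (20 * 8))
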