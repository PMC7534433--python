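"""Shared-ratio statistic, resampling nulls, sign test, pair sampling."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grnoverlap import (
    ConfigurationError,
    DegenerateTestError,
    EmptyAnalysisError,
    UndefinedRatioError,
    null_ratio_distribution,
    pairwise_ratio_distribution,
    sample_tf_pairs,
    shared_ratio,
    sign_test_exceeds,
    summarize_distribution,
)

from conftest import make_network


def six_number_oracle(values):
    """Independent six-number summary: manual linear interpolation between
    order statistics (type-7 quartiles), no numpy quantile machinery."""
    xs = sorted(values)
    n = len(xs)

    def quantile(p):
        h = (n - 1) * p
        lo = math.floor(h)
        if lo == n - 1:
            return xs[-1]
        return xs[lo] + (h - lo) * (xs[lo + 1] - xs[lo])

    return {
        "minimum": xs[0],
        "q1": quantile(0.25),
        "median": quantile(0.5),
        "q3": quantile(0.75),
        "maximum": xs[-1],
        "mean": sum(xs) / n,
    }


class TestSharedRatio:
    @pytest.mark.parametrize(
        "na, nb, shared, expected",
        [
            (5, 10, 2, 0.4),        # the statistic's worked example
            (7, 7, 7, 1.0),         # identical sets
            (4, 6, 0, 0.0),         # disjoint sets
            (79, 866, 12, 12 / 79),  # focal-TF vs 12DAA DEG geometry
            (79, 130, 4, 4 / 79),    # focal-TF vs 22DAA DEG geometry
        ],
    )
    def test_known_ratios(self, na, nb, shared, expected):
        common = {f"c{i}" for i in range(shared)}
        a = common | {f"a{i}" for i in range(na - shared)}
        b = common | {f"b{i}" for i in range(nb - shared)}
        rec = shared_ratio(a, b)
        assert rec.intersection == shared
        assert rec.ratio == pytest.approx(expected, abs=0)

    def test_one_empty_set_gives_zero_with_sizes(self):
        rec = shared_ratio(set(), {"g1", "g2"})
        assert (rec.size_a, rec.size_b, rec.ratio) == (0, 2, 0.0)

    def test_two_empty_sets_undefined(self):
        with pytest.raises(UndefinedRatioError):
            shared_ratio(set(), set())

    @given(
        a=st.sets(st.integers(0, 40), min_size=1, max_size=20),
        b=st.sets(st.integers(0, 40), min_size=1, max_size=20),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_symmetric_and_bounded(self, a, b):
        r1, r2 = shared_ratio(a, b), shared_ratio(b, a)
        assert r1.ratio == r2.ratio
        assert 0 <= r1.ratio <= 1
        assert (r1.ratio == 0) == (not a & b)
        assert (r1.ratio == 1) == (len(a & b) == min(len(a), len(b)))

    @given(
        a=st.sets(st.integers(0, 40), min_size=1, max_size=20),
        b=st.sets(st.integers(0, 40), min_size=1, max_size=20),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_monotone_under_growth(self, a, b):
        base = shared_ratio(a, b).ratio
        fresh = max(a | b) + 1
        grown = shared_ratio(a | {fresh}, b | {fresh}).ratio
        assert grown >= base or math.isclose(grown, base)
        # adding to only the larger set leaves the ratio unchanged
        larger, smaller = (a, b) if len(a) >= len(b) else (b, a)
        assert shared_ratio(smaller, larger | {fresh}).ratio == pytest.approx(
            shared_ratio(smaller, larger).ratio
        )


class TestSummarize:
    def test_all_zero(self):
        s = summarize_distribution([0, 0, 0, 0])
        assert (s.n, s.minimum, s.q1, s.median, s.mean, s.q3, s.maximum) == \
            (4, 0, 0, 0, 0, 0, 0)

    def test_three_points(self):
        s = summarize_distribution([0.0, 0.5, 1.0])
        assert s.median == 0.5 and s.mean == 0.5

    def test_eleven_evenly_spaced(self):
        s = summarize_distribution(np.linspace(0, 1, 11))
        assert s.q1 == pytest.approx(0.25)
        assert s.q3 == pytest.approx(0.75)

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            summarize_distribution([])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_matches_brute_force_oracle(self, values):
        s = summarize_distribution(values)
        oracle = six_number_oracle(values)
        for name, expected in oracle.items():
            assert getattr(s, name) == pytest.approx(expected, abs=1e-12)
        assert s.minimum <= s.q1 <= s.median <= s.q3 <= s.maximum
        assert s.minimum <= s.mean <= s.maximum


class TestSignTest:
    def test_nine_below_one_above_closed_form(self):
        # P(X >= 9 | n=10, p=1/2) = (C(10,9) + C(10,10)) / 2^10 = 11/1024
        null = [0.1] * 9 + [0.9]
        p = sign_test_exceeds(0.5, null, "greater")
        assert p == pytest.approx(float(Fraction(11, 1024)), rel=1e-12)

    def test_observed_above_every_sample(self):
        p = sign_test_exceeds(1.0, [0.0] * 1000, "greater")
        assert p == pytest.approx(0.5 ** 1000, rel=1e-9)
        assert p < 1e-300

    def test_observed_at_median_two_sided(self):
        null = np.linspace(0, 1, 101)
        assert sign_test_exceeds(0.5, null, "two_sided") == pytest.approx(1.0)

    def test_all_ties_degenerate(self):
        with pytest.raises(DegenerateTestError):
            sign_test_exceeds(0.3, [0.3, 0.3, 0.3])

    def test_empty_null_rejected(self):
        with pytest.raises(ConfigurationError):
            sign_test_exceeds(0.3, [])

    def test_less_is_mirror_of_greater(self):
        null = [0.1] * 3 + [0.9] * 7
        p_g = sign_test_exceeds(0.5, null, "greater")
        p_l = sign_test_exceeds(0.5, null, "less")
        # with 3 below / 7 above: P(X>=3) and P(X<=3) on Binomial(10, 1/2)
        assert p_g == pytest.approx(float(Fraction(968, 1024)))
        assert p_l == pytest.approx(float(Fraction(176, 1024)))


class TestSampleTfPairs:
    def test_family_of_three_gives_six_pairs(self, rng):
        pairs = sample_tf_pairs(["x", "y", "z"], 1000, rng)
        assert len(pairs) == 6
        assert set(pairs) == set(itertools.permutations(["x", "y", "z"], 2))

    def test_family_of_two_capped_at_two(self, rng):
        assert len(sample_tf_pairs(["x", "y"], 1000, rng)) == 2

    def test_fifty_tfs_thousand_unique_pairs(self, rng):
        frame = [f"tf{i}" for i in range(50)]
        pairs = sample_tf_pairs(frame, 1000, rng)
        assert len(pairs) == len(set(pairs)) == 1000
        assert all(a != b for a, b in pairs)

    def test_reproducible_given_seed(self):
        frame = [f"tf{i}" for i in range(30)]
        assert sample_tf_pairs(frame, 100, 7) == sample_tf_pairs(frame, 100, 7)

    def test_too_small_frame(self, rng):
        with pytest.raises(ConfigurationError):
            sample_tf_pairs(["only"], 10, rng)


def toy_network():
    """Three regulators with hand-checkable target sets."""
    edges = []
    targets = {"tf1": ["g1", "g2", "g3"], "tf2": ["g3", "g4"], "tf3": ["g5"]}
    for tf, tgts in targets.items():
        edges += [(tf, t, 1.0 + i) for i, t in enumerate(tgts)]
    return make_network(edges)


class TestNullDistribution:
    def test_matches_exhaustive_enumeration(self, rng):
        net = toy_network()
        reference = {"g1", "g3", "g5"}
        # by hand: tf1 → 2/3, tf2 → 1/2, tf3 → 1/1
        expected = sorted([2 / 3, 1 / 2, 1.0])
        records, summary = null_ratio_distribution(net, reference, 3, rng)
        assert sorted(r.ratio for r in records) == pytest.approx(expected)
        assert summary.n == 3

    def test_no_intersection_gives_all_zero_summary(self, rng):
        records, summary = null_ratio_distribution(
            toy_network(), {"x1", "x2"}, 3, rng
        )
        assert {r.ratio for r in records} == {0.0}
        assert (summary.minimum, summary.median, summary.mean, summary.maximum) \
            == (0, 0, 0, 0)

    def test_same_seed_identical_sequence(self):
        net = toy_network()
        rec1, _ = null_ratio_distribution(net, {"g1"}, 3, 42, replace=True)
        rec2, _ = null_ratio_distribution(net, {"g1"}, 3, 42, replace=True)
        assert rec1 == rec2

    def test_oversampling_without_replacement_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            null_ratio_distribution(toy_network(), {"g1"}, 10, rng)

    def test_exclusion_removes_focal_from_frame(self, rng):
        records, _ = null_ratio_distribution(
            toy_network(), {"g1"}, 2, rng, exclude=["tf1"]
        )
        assert {r.id_a for r in records} == {"tf2", "tf3"}


class TestPairwiseDistribution:
    def test_identical_and_disjoint_pairs(self):
        net = make_network(
            [("tf1", "g1", 1.0), ("tf1", "g2", 1.0),
             ("tf2", "g1", 1.0), ("tf2", "g2", 1.0),
             ("tf3", "g9", 1.0)]
        )
        records, _ = pairwise_ratio_distribution(
            net, [("tf1", "tf2"), ("tf1", "tf3")]
        )
        assert [r.ratio for r in records] == [1.0, 0.0]

    def test_all_ordered_pairs_match_brute_force(self, rng):
        config_targets = {
            "tf1": {"g1", "g2", "g3"}, "tf2": {"g2", "g3", "g4"},
            "tf3": {"g1"}, "tf4": {"g5", "g6"},
        }
        net = make_network(
            [(tf, t, 1.0) for tf, tgts in config_targets.items() for t in tgts]
        )
        pairs = list(itertools.permutations(config_targets, 2))
        records, summary = pairwise_ratio_distribution(net, pairs)
        brute = [
            len(config_targets[a] & config_targets[b])
            / min(len(config_targets[a]), len(config_targets[b]))
            for a, b in pairs
        ]
        assert [r.ratio for r in records] == pytest.approx(brute)
        oracle = six_number_oracle(brute)
        assert summary.n == 12
        assert summary.median == pytest.approx(oracle["median"])
        assert summary.mean == pytest.approx(oracle["mean"])

    def test_empty_member_pairs_dropped_then_empty_analysis(self, caplog):
        net = toy_network()
        with caplog.at_level("WARNING"):
            records, _ = pairwise_ratio_distribution(
                net, [("tf1", "tf2"), ("tf1", "ghost")]
            )
        assert len(records) == 1
        assert "dropped 1" in caplog.text
        with pytest.raises(EmptyAnalysisError):
            pairwise_ratio_distribution(net, [("ghost", "phantom")])
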