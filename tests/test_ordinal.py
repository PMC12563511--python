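"""Ordinal-pattern core: rank extraction, distributions, PE and PTIRR."""

import itertools
import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import msptirr as mp
from msptirr import InsufficientDataError, InvalidInputError, ParameterError
from msptirr.ordinal import PatternDistribution

from oracles import (
    naive_amplitude_permutation,
    naive_pattern_counts,
    naive_pe,
    naive_ptirr,
)


class TestAmplitudePermutation:
    @pytest.mark.parametrize(
        "vector, expected",
        [
            ((4, 7, 2), (2, 3, 1)),
            ((5, 5, 3), (2, 2, 1)),
            ((3, 3, 3), (1, 1, 1)),
            ((-1.5, -1.5, -1.5, -1.5), (1, 1, 1, 1)),
            ((1, 2), (1, 2)),
            ((2, 1), (2, 1)),
            ((0.1, 0.4, 0.2, 0.3), (1, 4, 2, 3)),
            ((2, 1, 2), (2, 1, 2)),
        ],
    )
    def test_examples(self, vector, expected):
        assert mp.amplitude_permutation(vector) == expected

    def test_matches_naive_on_random_vectors(self, rng):
        for _ in range(300):
            m = rng.integers(2, 7)
            # mix continuous values and small-alphabet values (forcing ties)
            if rng.random() < 0.5:
                vec = tuple(rng.normal(size=m))
            else:
                vec = tuple(int(v) for v in rng.integers(0, 3, size=m))
            assert mp.amplitude_permutation(vec) == naive_amplitude_permutation(vec)

    def test_non_finite_rejected(self):
        with pytest.raises(InvalidInputError):
            mp.amplitude_permutation((1.0, math.nan, 2.0))
        with pytest.raises(InvalidInputError):
            mp.amplitude_permutation((1.0, math.inf))

    def test_too_short_rejected(self):
        with pytest.raises(ParameterError):
            mp.amplitude_permutation((1.0,))

    def test_tie_tolerance_groups_near_values(self):
        assert mp.amplitude_permutation((1.0, 1.0005, 2.0), tie_tol=1e-2) == (1, 1, 3)
        assert mp.amplitude_permutation((1.0, 1.0005, 2.0), tie_tol=0.0) == (1, 2, 3)


class TestBackwardPermutation:
    @pytest.mark.parametrize(
        "forward, expected",
        [
            ((2, 3, 1), (1, 3, 2)),
            ((1, 2, 3), (3, 2, 1)),
            ((1, 1, 1), (1, 1, 1)),
        ],
    )
    def test_examples(self, forward, expected):
        assert mp.backward_permutation(forward) == expected

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ParameterError):
            mp.backward_permutation((0, 1, 2))

    def test_tie_rule_reversal_theorem_exhaustive(self):
        """Reversing the window reverses the rank tuple — checked over every
        value tuple of length 2..4 on the alphabet {1,2,3,4}."""
        for m in (2, 3, 4):
            for vec in itertools.product((1, 2, 3, 4), repeat=m):
                fwd = mp.amplitude_permutation(vec)
                rev = mp.amplitude_permutation(vec[::-1])
                assert rev == mp.backward_permutation(fwd)

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=2,
            max_size=8,
        )
    )
    def test_tie_rule_reversal_theorem_floats(self, vec):
        fwd = mp.amplitude_permutation(vec)
        assert mp.amplitude_permutation(vec[::-1]) == fwd[::-1]


class TestPatternDistribution:
    def test_strictly_increasing_series(self):
        d = mp.pattern_distribution([1, 2, 3, 4, 5], m=3, tau=1)
        assert d.forward_prob == {(1, 2, 3): 1.0}
        assert (d.U, d.V) == (1, 2)
        assert d.n_vectors == 3

    def test_alternating_series(self):
        d = mp.pattern_distribution([1, 2, 1, 2, 1], m=2, tau=1)
        assert d.forward_prob == {(1, 2): 0.5, (2, 1): 0.5}
        assert (d.U, d.V) == (2, 2)

    def test_constant_series(self):
        for m, tau in ((2, 1), (3, 2), (4, 3)):
            d = mp.pattern_distribution([7.0] * 30, m=m, tau=tau)
            assert d.forward_prob == {(1,) * m: 1.0}
            assert (d.U, d.V) == (1, 1)

    def test_too_short_names_minimum_length(self):
        with pytest.raises(InsufficientDataError, match="5"):
            mp.pattern_distribution([1, 2, 3, 4], m=3, tau=2)

    def test_invariants_on_random_series(self, rng):
        for _ in range(50):
            x = rng.normal(size=rng.integers(10, 80))
            m = int(rng.integers(2, 5))
            tau = int(rng.integers(1, 4))
            if x.size < (m - 1) * tau + 1:
                continue
            d = mp.pattern_distribution(x, m=m, tau=tau)
            assert sum(d.forward_prob.values()) == pytest.approx(1.0)
            assert d.U <= d.V <= 2 * d.U
            assert d.n_vectors == x.size - (m - 1) * tau
            for pat, c in d.counts.items():
                assert d.forward_prob[pat] == pytest.approx(c / d.n_vectors)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(8, 51))
            x = rng.normal(size=n)
            if rng.random() < 0.3:
                x = np.round(x)  # force ties
            for m in (2, 3, 4):
                for tau in (1, 2, 3):
                    if n < (m - 1) * tau + 1:
                        continue
                    d = mp.pattern_distribution(x, m=m, tau=tau)
                    counts, n_vec = naive_pattern_counts(list(x), m, tau)
                    assert dict(d.counts) == dict(counts)
                    assert d.n_vectors == n_vec

    def test_json_roundtrip(self, rng):
        d = mp.pattern_distribution(rng.normal(size=40), m=3, tau=1)
        d2 = PatternDistribution.from_json(d.to_json())
        assert dict(d2.counts) == dict(d.counts)
        assert (d2.m, d2.n_vectors) == (d.m, d.n_vectors)
        json.loads(d.to_json())  # valid JSON


def _dist_from_probs(probs: dict, n=1000):
    counts = {p: int(round(q * n)) for p, q in probs.items() if q > 0}
    total = sum(counts.values())
    m = len(next(iter(probs)))
    return PatternDistribution(counts=counts, m=m, n_vectors=total)


class TestPermutationEntropy:
    def test_uniform_six_patterns_is_log6(self):
        probs = {p: 1 / 6 for p in itertools.permutations((1, 2, 3))}
        d = _dist_from_probs(probs, n=600)
        assert mp.permutation_entropy(d) == pytest.approx(math.log(6), abs=1e-12)

    def test_degenerate_distribution_is_zero(self):
        d = _dist_from_probs({(1, 2, 3): 1.0})
        assert mp.permutation_entropy(d) == 0.0

    def test_fair_binary_is_log2(self):
        d = _dist_from_probs({(1, 2): 0.5, (2, 1): 0.5})
        assert mp.permutation_entropy(d) == pytest.approx(math.log(2), abs=1e-12)

    def test_base_and_normalization_options(self):
        probs = {p: 1 / 6 for p in itertools.permutations((1, 2, 3))}
        d = _dist_from_probs(probs, n=600)
        assert mp.permutation_entropy(d, base=2) == pytest.approx(math.log2(6))
        assert mp.permutation_entropy(d, normalized=True) == pytest.approx(1.0)

    def test_range_invariant(self, rng):
        for _ in range(30):
            m = int(rng.integers(2, 5))
            d = mp.pattern_distribution(rng.normal(size=60), m=m, tau=1)
            h = mp.permutation_entropy(d)
            assert 0.0 <= h <= math.log(math.factorial(m)) + 1e-12


class TestPTIRR:
    def test_symmetric_distribution_is_zero(self):
        d = _dist_from_probs({(1, 2, 3): 0.3, (3, 2, 1): 0.3, (1, 3, 2): 0.2, (2, 3, 1): 0.2})
        assert mp.permutation_time_irreversibility(d) == pytest.approx(0.0, abs=1e-15)

    def test_pure_ramp_distribution_is_one(self):
        d = _dist_from_probs({(1, 2, 3): 1.0})
        assert mp.permutation_time_irreversibility(d) == pytest.approx(1.0)

    def test_three_quarters_example(self):
        d = _dist_from_probs({(1, 2, 3): 0.75, (3, 2, 1): 0.25})
        assert mp.permutation_time_irreversibility(d) == pytest.approx(0.5)

    def test_matches_naive_and_stays_in_range(self, rng):
        for _ in range(100):
            x = rng.normal(size=int(rng.integers(10, 50)))
            d = mp.pattern_distribution(x, m=3, tau=1)
            counts, n_vec = naive_pattern_counts(list(x), 3, 1)
            v = mp.permutation_time_irreversibility(d)
            assert v == pytest.approx(naive_ptirr(counts, n_vec), abs=1e-12)
            assert 0.0 <= v <= 1.0

    def test_time_reversal_invariance_from_same_counts(self, rng):
        """PTIRR computed from forward counts equals PTIRR of the reversed
        series' counts exactly (the pairwise identity makes the statistic
        symmetric), up to boundary-window bookkeeping which vanishes when
        the window set is identical."""
        x = rng.normal(size=200)
        d_fwd = mp.pattern_distribution(x, m=3, tau=1)
        d_rev = mp.pattern_distribution(x[::-1], m=3, tau=1)
        # reversed series has the same windows read backward: same pair sums
        v_fwd = mp.permutation_time_irreversibility(d_fwd)
        v_rev = mp.permutation_time_irreversibility(d_rev)
        assert v_fwd == pytest.approx(v_rev, abs=1e-12)

    def test_gaussian_null_and_entropy(self, gaussian_long):
        d = mp.pattern_distribution(gaussian_long, m=3, tau=2)
        assert mp.permutation_time_irreversibility(d) < 0.02
        assert abs(mp.permutation_entropy(d) - math.log(6)) < 0.01
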