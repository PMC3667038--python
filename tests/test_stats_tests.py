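"""The Mann-Whitney machinery is checked against full enumeration, scipy,
and direct-formula oracles."""

import math
from itertools import combinations

import numpy as np
import pytest
import scipy.stats

from disorderscape.stats_tests import (
    Method,
    Tail,
    bin_distribution,
    mann_whitney,
    pearson_r,
)


def enumeration_p(x, y, tail):
    """Independent oracle: U by pair counting over every group labeling."""
    def u_of(xs, ys):
        return sum(
            1.0 if xv > yv else 0.5 if xv == yv else 0.0 for xv in xs for yv in ys
        )

    n1 = len(x)
    pooled = list(x) + list(y)
    u_obs = u_of(x, y)
    mu = n1 * len(y) / 2.0
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_of(xs, ys)
        total += 1
        if tail == "one_less":
            hits += u <= u_obs
        elif tail == "one_greater":
            hits += u >= u_obs
        else:
            hits += abs(u - mu) >= abs(u_obs - mu)
    return hits / total


class TestMannWhitneyExact:
    def test_small_sample_one_sided(self):
        res = mann_whitney([1, 2], [3, 4], "one_less")
        assert res.U == 0
        assert res.method is Method.EXACT
        assert res.p_value == pytest.approx(1 / 6, abs=1e-15)

    def test_identical_samples_two_sided(self):
        assert mann_whitney([5, 5, 5], [5, 5, 5], "two").p_value == 1.0

    def test_fully_separated_extreme(self):
        res = mann_whitney(list(range(1, 9)), list(range(9, 17)), "one_less")
        assert res.p_value == pytest.approx(1 / math.comb(16, 8), abs=1e-15)

    @pytest.mark.parametrize("tail", ["one_less", "one_greater", "two"])
    def test_matches_enumeration_with_ties(self, tail):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n1, n2 = rng.integers(1, 7, size=2)
            x = rng.integers(0, 5, size=n1).tolist()  # ties likely
            y = rng.integers(0, 5, size=n2).tolist()
            got = mann_whitney(x, y, tail).p_value
            assert got == pytest.approx(enumeration_p(x, y, tail), abs=1e-12)

    def test_matches_scipy_exact_tie_free(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n1, n2 = rng.integers(2, 7, size=2)
            pooled = rng.permutation(np.arange(20, dtype=float))
            x, y = pooled[:n1].tolist(), pooled[n1 : n1 + n2].tolist()
            ours = mann_whitney(x, y, "one_greater").p_value
            ref = scipy.stats.mannwhitneyu(x, y, alternative="greater",
                                           method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_tail_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=4).tolist()
            y = rng.normal(size=5).tolist()
            assert mann_whitney(x, y, "one_greater").p_value == pytest.approx(
                mann_whitney(y, x, "one_less").p_value, abs=1e-12
            )

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestMannWhitneyNormalApprox:
    def test_used_above_exact_limit(self):
        x = list(range(20))
        y = list(range(5, 25))
        assert mann_whitney(x, y).method is Method.NORMAL_APPROX

    def test_close_to_exact_at_boundary(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            pooled = rng.permutation(np.arange(16, dtype=float))
            x, y = pooled[:8].tolist(), pooled[8:].tolist()
            exact = mann_whitney(x, y, "one_greater").p_value
            approx = mann_whitney(x, y, "one_greater", exact_limit=0).p_value
            assert abs(exact - approx) < 0.01

    def test_detects_strong_shift(self):
        rng = np.random.default_rng(5)
        x = rng.normal(1.0, 1.0, size=40).tolist()
        y = rng.normal(0.0, 1.0, size=40).tolist()
        assert mann_whitney(x, y, "one_greater").p_value < 0.01

    def test_tie_corrected_matches_scipy(self):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 6, size=30).astype(float).tolist()
        y = rng.integers(0, 6, size=25).astype(float).tolist()
        ours = mann_whitney(x, y, "two").p_value
        ref = scipy.stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
        assert ours == pytest.approx(ref, rel=1e-6)


class TestPearson:
    def test_exact_collinearity(self):
        assert pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        x = [0.0, 1.0, 2.0, 3.0]
        y = [0.0, 1.0, 2.0, 10.0]
        n = len(x)
        sx, sy = sum(x), sum(y)
        sxy = sum(a * b for a, b in zip(x, y))
        sxx = sum(a * a for a in x)
        syy = sum(b * b for b in y)
        expected = (n * sxy - sx * sy) / math.sqrt(
            (n * sxx - sx * sx) * (n * syy - sy * sy)
        )
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestBinDistribution:
    def test_boundary_assignment(self):
        _, counts = bin_distribution([0.0, 4.9, 5.0], bin_width=5)
        assert counts[0] == 2 and counts[1] == 1

    def test_empty_input(self):
        _, counts = bin_distribution([], bin_width=5)
        assert counts.sum() == 0

    def test_final_bin_closed_at_100(self):
        _, counts = bin_distribution([100.0], bin_width=5)
        assert counts[-1] == 1

    def test_counts_conserved(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0, 100, size=500)
        _, counts = bin_distribution(values, bin_width=7)
        assert counts.sum() == 500

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            bin_distribution([101.0])
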