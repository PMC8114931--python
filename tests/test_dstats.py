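"""D / f4 statistics and the block jackknife."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from admixkit import (
    PanelError,
    block_jackknife,
    d_statistic,
    f2,
    f4,
    f4_ratio,
    f4_vector,
    site_patterns,
    triplet_sweep,
)
from admixkit.dstats import canonical_triplet
from conftest import make_panel


@pytest.mark.parametrize(
    "freqs, expected",
    [
        ((0, 1, 1, 0), (1.0, 0.0)),   # fixed ABBA
        ((1, 0, 1, 0), (0.0, 1.0)),   # fixed BABA
        ((0.5, 0.5, 1, 0), (0.25, 0.25)),  # p1 = p2 forces symmetry
    ],
)
def test_site_pattern_terms(freqs, expected):
    abba, baba = site_patterns(*freqs)
    assert (abba, baba) == expected


class TestDStatistic:
    def test_identical_p1_p2_gives_zero(self):
        rng = np.random.default_rng(1)
        p = rng.random(40)
        freq = np.column_stack([p, p, rng.random(40), rng.random(40)])
        panel = make_panel(freq, n_blocks=4)
        res = d_statistic(panel, tuple(panel.lineage_ids))
        assert res.D == pytest.approx(0.0, abs=1e-15)

    def test_three_site_hand_enumeration(self):
        # patterns ABBA, BABA, ABBA -> D = (2 - 1) / 3
        freq = np.array([[0, 1, 1, 0], [1, 0, 1, 0], [0, 1, 1, 0]], float)
        panel = make_panel(freq, n_blocks=3)
        res = d_statistic(panel, tuple(panel.lineage_ids))
        assert res.D == pytest.approx(1 / 3)
        assert res.abba_sum == 2.0 and res.baba_sum == 1.0

    def test_no_informative_sites_flagged_not_raised(self):
        freq = np.zeros((10, 4))
        panel = make_panel(freq, n_blocks=2)
        res = d_statistic(panel, tuple(panel.lineage_ids))
        assert not res.defined and math.isnan(res.D)

    def test_fixed_alleles_match_integer_counts(self):
        rng = np.random.default_rng(7)
        freq = rng.integers(0, 2, size=(300, 4)).astype(float)
        panel = make_panel(freq, n_blocks=10)
        res = d_statistic(panel, tuple(panel.lineage_ids))
        p1, p2, p3, p4 = freq.T
        abba = int(np.sum((p1 == 0) & (p2 == 1) & (p3 == 1) & (p4 == 0)))
        baba = int(np.sum((p1 == 1) & (p2 == 0) & (p3 == 1) & (p4 == 0)))
        assert res.D == pytest.approx((abba - baba) / (abba + baba))

    def test_missing_lineage_sites_skipped(self):
        freq = np.array([[0, 1, 1, 0], [np.nan, 0, 1, 0], [1, 0, 1, 0]], float)
        panel = make_panel(freq, n_blocks=3)
        res = d_statistic(panel, tuple(panel.lineage_ids))
        assert res.n_sites == 2 and res.D == pytest.approx(0.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetry_under_pair_swaps(self, seed):
        rng = np.random.default_rng(seed)
        freq = rng.random((50, 4))
        panel = make_panel(freq, n_blocks=5)
        a, b, c, d = panel.lineage_ids
        # D: swapping P1 and P2 negates the numerator, keeps the denominator
        base = d_statistic(panel, (a, b, c, d)).D
        assert d_statistic(panel, (b, a, c, d)).D == pytest.approx(-base)
        # f4: antisymmetric under either pair swap, restored by both
        base4 = f4(panel, (a, b, c, d))
        assert f4(panel, (b, a, c, d)) == pytest.approx(-base4, abs=1e-14)
        assert f4(panel, (a, b, d, c)) == pytest.approx(-base4, abs=1e-14)
        assert f4(panel, (b, a, d, c)) == pytest.approx(base4, abs=1e-14)


class TestBlockJackknife:
    def test_zero_dispersion_flags_undefined_z(self):
        pb = np.tile([1.0, 4.0, 10.0], (5, 1))
        est, se, z = block_jackknife(pb)
        assert est == 0.25 and se == 0.0 and math.isnan(z)

    def test_three_block_hand_jackknife(self):
        pb = np.array([[1, 4, 10], [2, 4, 10], [3, 4, 10]], float)
        est, se, z = block_jackknife(pb)
        oracle_est, oracle_se = oracles.jackknife_unweighted(
            [1, 2, 3], [4, 4, 4]
        )
        assert est == pytest.approx(oracle_est) == 0.5
        # equal weights reduce the Busing formula to the plain delete-one SE
        assert se == pytest.approx(oracle_se)

    def test_point_estimate_is_blocking_invariant(self):
        rng = np.random.default_rng(2)
        freq = rng.random((1000, 4))
        d10 = d_statistic(make_panel(freq, n_blocks=10), ("L0", "L1", "L2", "L3"))
        d100 = d_statistic(make_panel(freq, n_blocks=100), ("L0", "L1", "L2", "L3"))
        assert d10.D == pytest.approx(d100.D, rel=1e-12)

    def test_se_shrinks_with_site_count(self):
        rng = np.random.default_rng(3)
        ses = []
        for n in (2_000, 32_000):
            freq = rng.random((n, 4))
            res = d_statistic(make_panel(freq, n_blocks=40),
                              ("L0", "L1", "L2", "L3"))
            ses.append(res.se)
        # 16x the sites should shrink SE by about 4x
        assert ses[1] < ses[0] / 2.5


class TestF4:
    def test_equal_pair_gives_zero(self):
        rng = np.random.default_rng(4)
        p = rng.random(30)
        freq = np.column_stack([p, p, rng.random(30), rng.random(30)])
        panel = make_panel(freq)
        assert f4(panel, tuple(panel.lineage_ids)) == pytest.approx(0.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_f2_decomposition_identity(self, seed):
        rng = np.random.default_rng(seed)
        freq = rng.random((60, 4))
        panel = make_panel(freq)
        a, b, c, d = panel.lineage_ids
        lhs = f4(panel, (a, b, c, d))
        rhs = 0.5 * (f2(panel, a, d) + f2(panel, b, c)
                     - f2(panel, a, c) - f2(panel, b, d))
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_ratio_of_quartet_to_itself_is_one(self):
        rng = np.random.default_rng(5)
        panel = make_panel(rng.random((100, 4)), n_blocks=5)
        q = tuple(panel.lineage_ids)
        ratio, se, stable = f4_ratio(panel, q, q)
        assert ratio == pytest.approx(1.0) and stable
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_unstable_denominator_flagged(self):
        rng = np.random.default_rng(6)
        p = rng.random(50)
        freq = np.column_stack([p, p, rng.random(50), rng.random(50)])
        panel = make_panel(freq, n_blocks=5)
        a, b, c, d = panel.lineage_ids
        _, _, stable = f4_ratio(panel, (a, c, b, d), (a, b, c, d))
        assert not stable


class TestTripletSweep:
    def test_four_ingroup_lineages_give_four_rows(self):
        rng = np.random.default_rng(8)
        panel = make_panel(rng.random((200, 5)), n_blocks=10)
        table = triplet_sweep(panel, panel.outgroup_id)
        assert len(table) == 4  # C(4,3)

    def test_canonical_orientation(self):
        assert canonical_triplet(("C", "A", "B")) == ("B", "C", "A")
        rng = np.random.default_rng(9)
        panel = make_panel(rng.random((100, 5)), n_blocks=5)
        table = triplet_sweep(panel, panel.outgroup_id)
        assert (table["P3"] < table["P1"]).all()
        assert (table["P1"] < table["P2"]).all()

    def test_flags_present_and_consistent(self):
        rng = np.random.default_rng(10)
        panel = make_panel(rng.random((200, 5)), n_blocks=10)
        table = triplet_sweep(panel, panel.outgroup_id)
        assert {"D", "SE", "Z", "p", "bonferroni_sig", "z3.3_sig"} <= set(table)
        # Bonferroni flag implies the raw p is small
        assert (table.loc[table.bonferroni_sig, "p"] * len(table) < 0.05).all()


class TestF4Vector:
    def test_covariance_symmetric_psd(self):
        rng = np.random.default_rng(11)
        panel = make_panel(rng.random((500, 5)), n_blocks=25)
        l = panel.lineage_ids
        qs = [(l[0], l[1], l[2], l[4]), (l[0], l[2], l[3], l[4])]
        vec = f4_vector(panel, qs, statistic="D")
        assert np.allclose(vec.S, vec.S.T)
        assert np.linalg.eigvalsh(vec.S).min() > -1e-12
        assert vec.values[0] == pytest.approx(d_statistic(panel, qs[0]).D)

    def test_diagonal_matches_jackknife_variance(self):
        rng = np.random.default_rng(12)
        panel = make_panel(rng.random((500, 5)), n_blocks=25)
        l = panel.lineage_ids
        q = (l[0], l[1], l[2], l[4])
        vec = f4_vector(panel, [q], statistic="D")
        se = d_statistic(panel, q).se
        # equal-weight jackknife variance should be close to the weighted SE
        assert math.sqrt(vec.S[0, 0]) == pytest.approx(se, rel=0.15)
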