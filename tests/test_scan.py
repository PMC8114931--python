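"""Windowed Dxy / fd / pi, permutation nulls and block detection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from admixkit import (
    build_windows,
    detect_blocks,
    permutation_test,
    scan_windows,
    window_dxy,
    window_fd,
    window_pi,
)
from admixkit.scan import dxy_sites
from conftest import make_panel


def sites(n):
    return np.arange(n)


class TestWindowDxy:
    def test_identical_fixed_frequencies_give_zero(self):
        freq = np.column_stack([np.ones(5), np.ones(5)])
        panel = make_panel(freq, polarized=True)
        assert window_dxy(panel, sites(5), "L0", "L1") == 0.0

    def test_fixed_differences_give_one(self):
        freq = np.column_stack([np.ones(5), np.zeros(5)])
        panel = make_panel(freq)
        assert window_dxy(panel, sites(5), "L0", "L1") == 1.0

    def test_four_site_hand_sum(self):
        pa = [0.0, 0.5, 1.0, 0.0]
        pb = [1.0, 0.5, 1.0, 0.0]
        panel = make_panel(np.column_stack([pa, pb]))
        assert window_dxy(panel, sites(4), "L0", "L1") == pytest.approx(0.375)

    def test_symmetric_in_lineages(self):
        rng = np.random.default_rng(0)
        panel = make_panel(rng.random((30, 2)))
        a = window_dxy(panel, sites(30), "L0", "L1")
        b = window_dxy(panel, sites(30), "L1", "L0")
        assert a == pytest.approx(b)

    def test_self_dxy_is_mean_heterozygosity_term(self):
        # Dxy of a lineage against an identical frequency vector reduces
        # to the cross-population term 2p(1-p), not within-population pi
        rng = np.random.default_rng(1)
        p = rng.random(40)
        panel = make_panel(np.column_stack([p, p]))
        expected = float(np.mean(2 * p * (1 - p)))
        assert window_dxy(panel, sites(40), "L0", "L1") == pytest.approx(expected)


class TestWindowFd:
    def test_p2_equals_p3_gives_one(self):
        rng = np.random.default_rng(2)
        p23 = rng.uniform(0.3, 0.9, 20)
        p1 = np.zeros(20)
        o = np.zeros(20)
        panel = make_panel(np.column_stack([p1, p23, p23, o]))
        q = tuple(panel.lineage_ids)
        assert window_fd(panel, sites(20), q) == pytest.approx(1.0)

    def test_p1_equals_p2_is_undefined(self):
        rng = np.random.default_rng(3)
        p = rng.random(20)
        panel = make_panel(np.column_stack([p, p, rng.random(20), np.zeros(20)]))
        q = tuple(panel.lineage_ids)
        assert math.isnan(window_fd(panel, sites(20), q))

    def test_two_site_hand_computation_with_switching_donor(self):
        # site 1: p2 > p3 -> PD = p2; site 2: p3 > p2 -> PD = p3
        p1 = np.array([0.0, 0.1])
        p2 = np.array([0.8, 0.2])
        p3 = np.array([0.5, 0.9])
        p4 = np.array([0.0, 0.0])
        panel = make_panel(np.column_stack([p1, p2, p3, p4]))
        q = tuple(panel.lineage_ids)

        def terms(a, b, c, d):
            return (1 - a) * b * c * (1 - d) - a * (1 - b) * c * (1 - d)

        num = terms(0.0, 0.8, 0.5, 0.0) + terms(0.1, 0.2, 0.9, 0.0)
        den = terms(0.0, 0.8, 0.8, 0.0) + terms(0.1, 0.9, 0.9, 0.0)
        assert window_fd(panel, sites(2), q) == pytest.approx(num / den)

    def test_fd_at_most_one_when_defined(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            freq = rng.random((10, 4))
            freq[:, 3] = 0.0  # polarized outgroup
            panel = make_panel(freq)
            fd = window_fd(panel, sites(10), tuple(panel.lineage_ids))
            assert math.isnan(fd) or fd <= 1.0 + 1e-12


class TestWindowPi:
    def test_single_site_closed_form(self):
        panel = make_panel(np.array([[0.5]]), called=4)
        assert window_pi(panel, sites(1), "L0") == pytest.approx(2 / 3)

    def test_monomorphic_window_is_zero(self):
        panel = make_panel(np.zeros((6, 1)), called=8)
        assert window_pi(panel, sites(6), "L0") == 0.0

    def test_three_site_hand_sum(self):
        panel = make_panel(np.array([[0.25], [0.5], [0.0]]), called=4)
        expected = (0.5 + 2 / 3 + 0.0) / 3
        assert window_pi(panel, sites(3), "L0") == pytest.approx(expected)


class TestPermutation:
    def test_observed_equal_to_every_null_gives_one(self):
        vals = np.full(20, 0.4)
        p = permutation_test(0.4, vals, 5, 100, "greater", seed=0)
        assert p == 1.0

    def test_floor_is_one_over_nperm_plus_one(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.uniform(0, 0.1, 99), [50.0]])
        # a window holding the single huge site beats every 1-site redraw
        p = permutation_test(50.0, vals[:-1], 1, 1000, "greater", seed=1)
        assert p == pytest.approx(1 / 1001)

    def test_exhaustive_enumeration_matches_manual_null(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        obs = 3.5  # mean of a 2-site window
        p = permutation_test(obs, vals, 2, 1, "greater", exhaustive=True)
        means = [np.mean(c) for c in itertools.combinations(vals, 2)]
        expected = (1 + sum(m >= obs for m in means)) / (1 + len(means))
        assert p == pytest.approx(expected)

    def test_direction_less(self):
        vals = np.arange(1, 11, dtype=float)
        p_low = permutation_test(1.0, vals, 1, 500, "less", seed=2)
        p_high = permutation_test(10.0, vals, 1, 500, "less", seed=2)
        assert p_low < 0.2 < p_high


class TestDetectBlocks:
    @staticmethod
    def scan_frame(dxy, fd):
        n = len(dxy)
        return pd.DataFrame(
            {
                "chrom": ["chr1"] * n,
                "start": np.arange(n) * 100,
                "end": (np.arange(n) + 1) * 100,
                "nsites": 10,
                "retained": True,
                "dxy": dxy,
                "fd": fd,
            }
        )

    def test_no_window_passes_gives_empty(self):
        scan = self.scan_frame(np.linspace(0.2, 0.3, 10), np.zeros(10))
        assert detect_blocks(scan).empty

    def test_runs_ranked_by_length(self):
        dxy = np.full(20, 0.5)
        fd = np.zeros(20)
        dxy[2:7] = 0.01   # run of 5
        fd[2:7] = 0.9
        dxy[12:15] = 0.01  # run of 3
        fd[12:15] = 0.9
        blocks = detect_blocks(self.scan_frame(dxy, fd), dxy_quantile=0.5,
                               min_run=3, merge_gaps=0)
        assert list(blocks["n_windows"]) == [5, 3]
        assert blocks.iloc[0]["start"] == 200 and blocks.iloc[0]["end"] == 700

    def test_single_window_gap_merged(self):
        dxy = np.full(20, 0.5)
        fd = np.zeros(20)
        dxy[2:10] = 0.01
        fd[2:10] = 0.9
        fd[5] = 0.0  # one failing window inside the run
        blocks = detect_blocks(self.scan_frame(dxy, fd), dxy_quantile=0.5,
                               min_run=3, merge_gaps=1)
        assert len(blocks) == 1 and blocks.iloc[0]["n_windows"] == 8


class TestScanDriver:
    def test_scan_table_columns_and_pvalues(self):
        rng = np.random.default_rng(6)
        freq = rng.random((300, 4))
        freq[:, 3] = 0.0
        panel = make_panel(freq, pos=np.arange(300) * 100 + 1)
        windows = build_windows(panel, 5_000)
        q = tuple(panel.lineage_ids)
        table = scan_windows(panel, windows, dxy_pair=("L1", "L2"), quartet=q,
                             pi_lineages=["L0"], n_perm=50, seed=0)
        assert {"dxy", "fd", "pi_L0", "p_dxy", "p_fd"} <= set(table.columns)
        assert table["p_dxy"].between(0, 1).all()
        # dxy consistent with direct per-window evaluation
        for i in range(len(windows)):
            expected = window_dxy(panel, windows.site_membership[i], "L1", "L2")
            assert table["dxy"][i] == pytest.approx(expected)

    def test_replacing_p3_by_p2_drives_fd_to_one(self):
        rng = np.random.default_rng(7)
        p2 = rng.uniform(0.2, 0.9, 200)
        freq = np.column_stack([np.zeros(200), p2, p2, np.zeros(200)])
        panel = make_panel(freq, pos=np.arange(200) * 100 + 1)
        windows = build_windows(panel, 5_000)
        table = scan_windows(panel, windows, dxy_pair=("L1", "L2"),
                             quartet=tuple(panel.lineage_ids))
        assert np.allclose(table["fd"].dropna(), 1.0)
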