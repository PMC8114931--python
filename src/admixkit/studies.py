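"""Reproducible synthetic benchmark studies.

Each function simulates data under a known admixture graph (or mixture /
codon process), runs the corresponding estimator end to end, and returns
the measured quantities.  These studies define the package's calibration
and parameter-recovery benchmarks; the acceptance tests assert on their
outputs and ``scripts/acceptance.py`` reports them.

Problem sizes default to desk-scale study conditions: 20 kb-site panels
with 100 jackknife blocks for null calibration, 50 kb-site panels for
parameter recovery, 50 kb windows with ~50 variants each for scans, and
n = 2000 branch lengths for the mixture test.
"""

from __future__ import annotations

import itertools

import numpy as np

from .dstats import d_statistic, f4_ratio, f4_vector, triplet_sweep
from .graph import AdmixtureGraph, ScenarioModel, compare_scenarios
from .panel import assign_blocks, build_windows
from .quibl import quibl_fit
from .scan import detect_blocks, dxy_sites, permutation_test, scan_windows
from .selection import foreground_background_test, ng86_pairwise
from .simulate import (
    SimulationConfig,
    simulate_codon_pair,
    simulate_frequencies,
    simulate_scan_panel,
    simulate_triplet_lengths,
)

__all__ = [
    "reference_admixed_graph",
    "symmetric_null_graph",
    "deep_divergence_tree",
    "ranking_scenarios",
    "triplet_sweep_count",
    "null_z_calibration",
    "perfect_fit_recovery",
    "alpha_recovery",
    "scenario_ranking",
    "scan_detection",
    "permutation_uniformity",
    "quibl_recovery",
    "neutral_omega_recovery",
    "foreground_background_study",
]


# ------------------------------------------------------- reference graphs


def reference_admixed_graph(alpha: float = 0.3) -> AdmixtureGraph:
    """5-leaf graph: ((A,B),C) ingroup, outgroup O, and X admixed between
    the B and C branches with proportion ``alpha`` toward B."""
    return AdmixtureGraph(
        edges={
            ("R", "O"): 0.05, ("R", "I"): 0.02,
            ("I", "n1"): 0.02, ("I", "Cp"): 0.02,
            ("n1", "A"): 0.02, ("n1", "Bp"): 0.01,
            ("Bp", "B"): 0.02, ("Cp", "C"): 0.02,
            ("Bp", "X0"): 0.0, ("Cp", "X0"): 0.0,
            ("X0", "X"): 0.01,
        },
        admixture={"X0": ("Bp", "Cp", alpha)},
    )


def symmetric_null_graph() -> AdmixtureGraph:
    """4-leaf tree ((P1,P2),P3,O) with equal sister drifts: D's null."""
    return AdmixtureGraph(
        edges={
            ("R", "O"): 0.05, ("R", "I"): 0.02,
            ("I", "P3"): 0.02, ("I", "n"): 0.01,
            ("n", "P1"): 0.015, ("n", "P2"): 0.015,
        }
    )


def deep_divergence_tree() -> AdmixtureGraph:
    """4-leaf tree ((A,X),C,O) with deep drift on every branch.

    Long drift pushes leaf frequencies toward fixation, so between-lineage
    Dxy reflects near-fixed differences rather than shared polymorphism —
    the regime of diverged species where an introgressed block shows a
    clear low-Dxy signature.
    """
    return AdmixtureGraph(
        edges={
            ("R", "O"): 0.3, ("R", "I"): 0.1,
            ("I", "C"): 0.3, ("I", "n"): 0.1,
            ("n", "A"): 0.25, ("n", "X"): 0.25,
        }
    )


_RANKING_BASE = {
    ("R", "O"): 0.05, ("R", "I"): 0.02,
    ("I", "n1"): 0.015, ("I", "n2"): 0.015,
    ("n1", "Ap"): 0.01, ("Ap", "A"): 0.01,
    ("n1", "Bp"): 0.01, ("Bp", "B"): 0.01,
    ("n2", "Cp"): 0.01, ("Cp", "C"): 0.01,
    ("n2", "Dp"): 0.01, ("Dp", "D"): 0.01,
}


def ranking_scenarios(a1: float = 0.4, a2: float = 0.3):
    """Nested scenarios M1 (tree) .. M3 (both reticulations = truth).

    Two extra leaves X and Y either attach as plain sisters (tree
    scenarios) or as admixed lineages: X between the B and C branches
    (first reticulation), Y between the A and D branches (second).
    Returns (scenario dict, true graph).
    """

    def build(with_x: bool, with_y: bool) -> AdmixtureGraph:
        edges = dict(_RANKING_BASE)
        admix = {}
        if with_x:
            edges.update({("Bp", "X0"): 0.0, ("Cp", "X0"): 0.0, ("X0", "X"): 0.01})
            admix["X0"] = ("Bp", "Cp", a1)
        else:
            edges.update({("Bp", "X0"): 0.0, ("X0", "X"): 0.01})
        if with_y:
            edges.update({("Ap", "Y0"): 0.0, ("Dp", "Y0"): 0.0, ("Y0", "Y"): 0.01})
            admix["Y0"] = ("Ap", "Dp", a2)
        else:
            edges.update({("Dp", "Y0"): 0.0, ("Y0", "Y"): 0.01})
        return AdmixtureGraph(edges=edges, admixture=admix)

    scenarios = {
        "M1": build(False, False),
        "M2": build(True, False),
        "M3": build(True, True),
    }
    return scenarios, scenarios["M3"]


def _f2_quartets(leaves):
    return [(a, b, a, b) for a, b in itertools.combinations(leaves, 2)]


def _mixed_quartets(leaves):
    qs = [tuple(q) for q in itertools.combinations(leaves, 4)]
    return qs + _f2_quartets(leaves)


# ---------------------------------------------------------------- studies


def triplet_sweep_count(n_ingroup: int = 34, n_sites: int = 400, seed: int = 0):
    """Size of the all-triplets D sweep for ``n_ingroup`` lineages.

    Simulates a star-like panel of n_ingroup + 1 lineages and runs the
    full sweep; returns (row count, table).
    """
    labels = [f"L{i:02d}" for i in range(n_ingroup)] + ["OUT"]
    edges = {("R", lab): 0.02 for lab in labels}
    g = AdmixtureGraph(edges=edges)
    cfg = SimulationConfig(graph=g, n_sites=n_sites, seed=seed, outgroup="OUT")
    panel, _ = simulate_frequencies(cfg)
    panel = assign_blocks(panel, 20)
    table = triplet_sweep(panel, "OUT")
    return len(table), table


def null_z_calibration(
    n_replicates: int = 500,
    n_sites: int = 20_000,
    n_blocks: int = 100,
    z_threshold: float = 3.3,
    seed: int = 0,
):
    """|Z| exceedance rate of the D statistic under a no-admixture graph.

    Each replicate simulates an independent panel under the symmetric null
    tree and jackknifes one triplet's D.  The normal tail gives
    P(|Z| > 3.3) ~ 0.001; a calibrated jackknife should stay near that.
    """
    g = symmetric_null_graph()
    rng = np.random.default_rng(seed)
    zs = np.empty(n_replicates)
    for i in range(n_replicates):
        cfg = SimulationConfig(
            graph=g, n_sites=n_sites, seed=int(rng.integers(2**31)), outgroup="O"
        )
        panel, _ = simulate_frequencies(cfg)
        panel = assign_blocks(panel, n_blocks)
        zs[i] = d_statistic(panel, ("P1", "P2", "P3", "O")).Z
    frac = float(np.mean(np.abs(zs) > z_threshold))
    return {"fraction_exceeding": frac, "z_sd": float(np.std(zs)), "z": zs}


def perfect_fit_recovery(seed: int = 0, alpha: float = 0.3):
    """Fit the generating topology to its own exact expectations.

    The observed vector is F(theta*) with identity covariance; a correct
    fitter must drive the cost to ~0 and recover every identifiable
    parameter (alpha, free drifts, fused root-pair sum).
    """
    from .dstats import F4Vector
    from .graph import expected_f4

    g = reference_admixed_graph(alpha)
    qs = _mixed_quartets(g.leaves)
    F = np.array([expected_f4(g, q) for q in qs])
    obs = F4Vector(
        entries=[(tuple(q), float(v)) for q, v in zip(qs, F)],
        S=np.eye(len(qs)),
        statistic_kind="f4",
    )
    res = ScenarioModel(g, obs, scenario_id="generating").fit(restarts=3, seed=seed)
    fused = set(res.fused_root_edges or ())
    drift_errors = {}
    for e, d in res.drifts.items():
        if e in fused or d == 0.0 and g.edges[e] == 0.0:
            continue
        drift_errors[e] = abs(d - g.edges[e])
    root_sum_err = abs(
        sum(res.drifts[e] for e in fused) - sum(g.edges[e] for e in fused)
    )
    return {
        "minimal_error": res.minimal_error,
        "alpha_error": abs(res.alphas["X0"] - alpha),
        "max_drift_error": max(max(drift_errors.values()), root_sum_err),
        "fit": res,
    }


def alpha_recovery(
    alphas=(0.1, 0.3, 0.5),
    n_sites: int = 50_000,
    n_seeds: int = 20,
    n_blocks: int = 100,
    seed: int = 0,
):
    """Median |alpha_hat - alpha| for the f4-ratio and the graph fit.

    Data are simulated under the reference admixed graph; the f4-ratio
    uses the classic donor-proxy quartets f4(A,O;X,C)/f4(A,O;B,C), the
    graph fit uses the full mixed f4/f2 vector with jackknife covariance.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for alpha in alphas:
        g = reference_admixed_graph(alpha)
        ratio_err, fit_err = [], []
        for _ in range(n_seeds):
            cfg = SimulationConfig(
                graph=g, n_sites=n_sites, seed=int(rng.integers(2**31)),
                outgroup="O",
            )
            panel, _ = simulate_frequencies(cfg)
            panel = assign_blocks(panel, n_blocks)
            r, _, _ = f4_ratio(panel, ("A", "O", "X", "C"), ("A", "O", "B", "C"))
            ratio_err.append(abs(r - alpha))
            obs = f4_vector(panel, _mixed_quartets(panel.lineage_ids), "f4")
            fit = ScenarioModel(reference_admixed_graph(0.5), obs).fit(
                restarts=2, seed=int(rng.integers(2**31))
            )
            fit_err.append(abs(fit.alphas["X0"] - alpha))
        out[alpha] = {
            "ratio_median_error": float(np.median(ratio_err)),
            "fit_median_error": float(np.median(fit_err)),
        }
    return out


def scenario_ranking(
    n_seeds: int = 20,
    n_sites: int = 50_000,
    n_blocks: int = 100,
    restarts: int = 2,
    seed: int = 0,
):
    """Minimal errors of nested scenarios on reticulate synthetic data.

    Counts seeds where the full (true) model has the smallest error and
    where errors are monotone non-increasing M1 >= M2 >= M3.
    """
    scenarios, true_g = ranking_scenarios()
    rng = np.random.default_rng(seed)
    errors = []
    for _ in range(n_seeds):
        cfg = SimulationConfig(
            graph=true_g, n_sites=n_sites, seed=int(rng.integers(2**31)),
            outgroup="O",
        )
        panel, _ = simulate_frequencies(cfg)
        panel = assign_blocks(panel, n_blocks)
        obs = f4_vector(panel, _f2_quartets(panel.lineage_ids), "f4")
        fits = compare_scenarios(
            scenarios, obs, restarts=restarts, seed=int(rng.integers(2**31))
        )
        errors.append({f.scenario_id: f.minimal_error for f in fits})
    e = np.array([[d["M1"], d["M2"], d["M3"]] for d in errors])
    return {
        "n_seeds": n_seeds,
        "n_full_model_best": int(np.sum(e[:, 2] <= e.min(axis=1) + 1e-9)),
        "n_monotone": int(np.sum((e[:, 0] >= e[:, 1]) & (e[:, 1] >= e[:, 2]))),
        "median_errors": {
            "M1": float(np.median(e[:, 0])),
            "M2": float(np.median(e[:, 1])),
            "M3": float(np.median(e[:, 2])),
        },
        "errors": errors,
    }


def scan_detection(
    n_seeds: int = 20,
    n_sites: int = 5_000,
    spacing: int = 1_000,
    window_size: int = 50_000,
    block_windows: tuple[int, int] = (40, 50),
    seed: int = 0,
):
    """Recovery of a planted introgressed block by the window scan.

    A 5 Mb chromosome (100 windows of 50 kb, ~50 variants each) of deeply
    diverged lineages carries a 10-window block where the recipient X
    copies the donor C.  Detection uses low-Dxy / high-fd runs; recovery
    means >= 80% reciprocal overlap between the top-ranked detected block
    and the planted one.  The in-block Dxy-below-median and fd-above-mean
    contrasts are counted too.
    """
    g = deep_divergence_tree()
    lo, hi = block_windows[0] * window_size, block_windows[1] * window_size
    rng = np.random.default_rng(seed)
    overlaps, dxy_contrast, fd_contrast = [], 0, 0
    for _ in range(n_seeds):
        cfg = SimulationConfig(
            graph=g, n_sites=n_sites, seed=int(rng.integers(2**31)),
            outgroup="O", spacing=spacing,
        )
        panel, truth = simulate_scan_panel(cfg, ("chr1", lo, hi), "C", "X")
        windows = build_windows(panel, window_size)
        table = scan_windows(
            panel, windows, dxy_pair=("C", "X"), quartet=("A", "X", "C", "O")
        )
        blocks = detect_blocks(table, dxy_quantile=0.25, fd_threshold=0.5,
                               min_run=3)
        if blocks.empty:
            overlaps.append(0.0)
        else:
            b = blocks.iloc[0]
            inter = max(0, min(hi, b.end) - max(lo, b.start))
            overlaps.append(min(inter / (hi - lo), inter / (b.end - b.start)))
        in_block = (table.start >= lo) & (table.end <= hi)
        dxy_contrast += (
            table.loc[in_block, "dxy"].mean() < table["dxy"].median()
        )
        fd_contrast += (
            table.loc[in_block, "fd"].mean() > table["fd"].mean()
        )
    overlaps = np.array(overlaps)
    return {
        "n_seeds": n_seeds,
        "n_recovered": int(np.sum(overlaps >= 0.8)),
        "median_overlap": float(np.median(overlaps)),
        "n_dxy_below_median": int(dxy_contrast),
        "n_fd_above_mean": int(fd_contrast),
    }


def permutation_uniformity(
    n_windows: int = 500,
    sites_per_window: int = 10,
    n_perm: int = 200,
    seed: int = 0,
):
    """KS distance of null-permutation p-values from Uniform(0, 1).

    Under the symmetric null tree every window is exchangeable with the
    genome background, so one-sided Dxy p-values must be uniform up to
    the discreteness of n_perm draws.
    """
    from scipy import stats

    g = symmetric_null_graph()
    cfg = SimulationConfig(
        graph=g, n_sites=n_windows * sites_per_window, seed=seed, outgroup="O",
        spacing=100,
    )
    panel, _ = simulate_frequencies(cfg)
    site_vals = dxy_sites(panel, "P2", "P3")
    rng = np.random.default_rng(seed + 1)
    n = panel.n_sites
    pvals = []
    for w in range(n // sites_per_window):
        idx = np.arange(w * sites_per_window, (w + 1) * sites_per_window)
        obs = float(np.nanmean(site_vals[idx]))
        pvals.append(
            permutation_test(obs, site_vals, sites_per_window, n_perm,
                             "less", seed=int(rng.integers(2**31)))
        )
    ks = stats.kstest(pvals, "uniform").statistic
    return {"ks_distance": float(ks), "n_windows": len(pvals),
            "p_floor": 1.0 / (n_perm + 1)}


def quibl_recovery(
    n_seeds: int = 50,
    pi2: float = 0.5,
    C: float = 2.0,
    lam: float = 1.0,
    n: int = 2_000,
    seed: int = 0,
):
    """Mixture-model recovery on shifted-exponential branch lengths.

    Counts seeds where BIC prefers the mixture, where pi2_hat lands within
    +/-0.10 of truth, and whether every EM trajectory was monotone.
    """
    rng = np.random.default_rng(seed)
    preferred = pi2_ok = 0
    monotone = True
    pi2_hats = []
    for _ in range(n_seeds):
        x, _ = simulate_triplet_lengths(pi2, C, lam, n, int(rng.integers(2**31)))
        res = quibl_fit(x)
        preferred += res.preferred == 2
        pi2_hats.append(res.mix[1])
        pi2_ok += abs(res.mix[1] - pi2) <= 0.10
        traj = np.asarray(res.em_trajectory)
        if len(traj) > 1 and np.any(np.diff(traj) < -1e-8):
            monotone = False
    return {
        "n_seeds": n_seeds,
        "n_mixture_preferred": preferred,
        "n_pi2_within_010": pi2_ok,
        "median_pi2_hat": float(np.median(pi2_hats)),
        "all_em_monotone": monotone,
    }


def neutral_omega_recovery(
    n_seeds: int = 20, n_codons: int = 500, t: float = 0.15, seed: int = 0
):
    """Median NG86 omega_hat on codon pairs simulated with omega = 1."""
    rng = np.random.default_rng(seed)
    omegas = []
    for _ in range(n_seeds):
        a, b, _ = simulate_codon_pair(1.0, t, n_codons, int(rng.integers(2**31)))
        omegas.append(ng86_pairwise(a, b).omega)
    return {"median_omega": float(np.nanmedian(omegas)), "n_seeds": n_seeds}


def foreground_background_study(
    n_fg: int = 15,
    n_bg: int = 40,
    omega_fg: float = 0.6,
    omega_bg: float = 0.25,
    n_codons: int = 300,
    t: float = 0.15,
    n_perm: int = 1000,
    seed: int = 0,
):
    """End-to-end fg/bg dN/dS contrast on simulated codon alignments.

    Foreground genes evolve with elevated omega; the study reports the
    group means and the one-sided permutation p-value.
    """
    rng = np.random.default_rng(seed)

    def batch(k, omega):
        out = []
        for _ in range(k):
            a, b, _ = simulate_codon_pair(omega, t, n_codons,
                                          int(rng.integers(2**31)))
            out.append(ng86_pairwise(a, b).omega)
        return out

    fg = batch(n_fg, omega_fg)
    bg = batch(n_bg, omega_bg)
    res = foreground_background_test(fg, bg, n_perm=n_perm,
                                     seed=int(rng.integers(2**31)))
    return res
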