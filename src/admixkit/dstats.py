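"""Patterson's D and f-statistics with block-jackknife uncertainty.

For a quartet (P1, P2, P3, O) of derived-allele frequencies the per-site
site-pattern terms are

    ABBA = (1 - p1) * p2 * p3 * (1 - p4)
    BABA = p1 * (1 - p2) * p3 * (1 - p4)

and D = sum(ABBA - BABA) / sum(ABBA + BABA).  Significance comes from a
weighted delete-one block jackknife over contiguous genomic blocks, the
standard remedy for linkage between nearby sites.  f4 is the cross
allele-frequency contrast sum((p1-p2)(p3-p4))/n and the f4-ratio of two
suitable quartets estimates an admixture proportion.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import AlleleFrequencyPanel, PanelError

__all__ = [
    "site_patterns",
    "d_statistic",
    "f4",
    "f2",
    "f4_ratio",
    "block_jackknife",
    "block_jackknife_ratio",
    "triplet_sweep",
    "f4_vector",
    "DStatResult",
    "F4Vector",
]


def site_patterns(p1, p2, p3, p4):
    """Per-site ABBA and BABA terms from frequencies in [0, 1].

    Missing (NaN) frequencies propagate to NaN terms, which the callers
    skip; returns (abba, baba) arrays.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    abba = (1.0 - p1) * p2 * p3 * (1.0 - p4)
    baba = p1 * (1.0 - p2) * p3 * (1.0 - p4)
    return abba, baba


@dataclass
class DStatResult:
    """D statistic for one quartet with jackknife uncertainty."""

    quartet: tuple[str, str, str, str]
    D: float
    abba_sum: float
    baba_sum: float
    se: float
    Z: float
    n_sites: int
    per_block: np.ndarray  # (n_blocks, 3): numerator, denominator, weight

    @property
    def defined(self) -> bool:
        return math.isfinite(self.D)

    @property
    def p_value(self) -> float:
        """Two-sided normal p-value of Z."""
        if not math.isfinite(self.Z):
            return math.nan
        return math.erfc(abs(self.Z) / math.sqrt(2.0))


def _quartet_columns(panel: AlleleFrequencyPanel, quartet, require_distinct=False):
    # f4 admits repeated leaves (f2/f3 specialisations); D does not
    if require_distinct and len(set(quartet)) != 4:
        raise PanelError(f"quartet lineages must be distinct: {quartet}")
    return [panel.column(q) for q in quartet]


def _per_block(panel, num_site, den_site, informative):
    """Aggregate per-site numerator/denominator into per-block triples."""
    if panel.block_id is None:
        raise PanelError("panel has no jackknife blocks; call assign_blocks first")
    bid = panel.block_id
    n_blocks = int(bid.max()) + 1
    num = np.bincount(bid, weights=np.where(informative, num_site, 0.0), minlength=n_blocks)
    den = np.bincount(bid, weights=np.where(informative, den_site, 0.0), minlength=n_blocks)
    w = np.bincount(bid, weights=informative.astype(float), minlength=n_blocks)
    return np.column_stack([num, den, w])


def d_statistic(panel: AlleleFrequencyPanel, quartet) -> DStatResult:
    """Patterson's D for one ordered quartet (P1, P2, P3, O).

    Sites where any of the four lineages is missing are skipped for this
    quartet only (pairwise deletion).  When no informative site remains the
    result carries ``D = nan`` rather than raising.
    """
    cols = _quartet_columns(panel, quartet, require_distinct=True)
    abba, baba = site_patterns(*cols)
    usable = np.isfinite(abba) & np.isfinite(baba)
    num_site = np.where(usable, abba - baba, 0.0)
    den_site = np.where(usable, abba + baba, 0.0)
    informative = usable & (den_site > 0)

    per_block = _per_block(panel, num_site, den_site, informative)
    num, den = per_block[:, 0].sum(), per_block[:, 1].sum()
    n_inf = int(informative.sum())
    if den <= 0:
        return DStatResult(tuple(quartet), math.nan, 0.0, 0.0, math.nan, math.nan, 0, per_block)

    est, se, z = block_jackknife(per_block)
    abba_sum = float(np.where(informative, abba, 0.0).sum())
    baba_sum = float(np.where(informative, baba, 0.0).sum())
    return DStatResult(tuple(quartet), est, abba_sum, baba_sum, se, z, n_inf, per_block)


def block_jackknife(per_block: np.ndarray) -> tuple[float, float, float]:
    """Weighted delete-one block jackknife for a ratio statistic.

    ``per_block`` rows are (numerator, denominator, weight); the estimate is
    sum(num)/sum(den) and the standard error uses Busing-style weighting
    with block weights h_j = n / m_j:

        tau_j  = h_j * theta - (h_j - 1) * theta_{-j}
        var    = (1/g) * sum_j (tau_j - theta_J)^2 / (h_j - 1)

    Blocks with zero weight (no informative sites) are dropped.  When every
    delete-one estimate is identical the SE is 0 and Z is NaN (flagged
    undefined).
    """
    pb = np.asarray(per_block, dtype=float)
    pb = pb[pb[:, 2] > 0]
    g = len(pb)
    if g < 2:
        raise PanelError("jackknife needs >=2 blocks with informative sites")
    num, den, m = pb[:, 0], pb[:, 1], pb[:, 2]
    tot_num, tot_den, n = num.sum(), den.sum(), m.sum()
    if tot_den <= 0:
        raise PanelError("total denominator must be positive")
    theta = tot_num / tot_den
    loo = (tot_num - num) / (tot_den - den)
    if np.allclose(loo, loo[0], rtol=0.0, atol=0.0):
        return float(theta), 0.0, math.nan
    h = n / m
    theta_j = g * theta - float(np.sum((1.0 - m / n) * loo))
    tau = h * theta - (h - 1.0) * loo
    var = float(np.sum((tau - theta_j) ** 2 / (h - 1.0)) / g)
    se = math.sqrt(max(var, 0.0))
    z = theta / se if se > 0 else math.nan
    return float(theta), se, z


def block_jackknife_ratio(per_block_num: np.ndarray, per_block_den: np.ndarray):
    """Jackknife a ratio of two block-decomposed statistics (f4-ratio).

    Each argument is an (n_blocks, 2) array of (sum, weight); the point
    estimate is (sum num)/(sum den) and the SE comes from delete-one
    re-estimates with equal-block weighting.
    """
    a = np.asarray(per_block_num, dtype=float)
    b = np.asarray(per_block_den, dtype=float)
    tot_a, tot_b = a[:, 0].sum(), b[:, 0].sum()
    if tot_b == 0:
        raise PanelError("denominator f4 sums to zero")
    est = tot_a / tot_b
    loo_den = tot_b - b[:, 0]
    ok = loo_den != 0
    loo = (tot_a - a[ok, 0]) / loo_den[ok]
    g = int(ok.sum())
    if g < 2:
        return float(est), math.nan
    var = (g - 1) / g * float(np.sum((loo - loo.mean()) ** 2))
    return float(est), math.sqrt(max(var, 0.0))


# ------------------------------------------------------------------- f-stats


def _f4_blocks(panel, quartet):
    cols = _quartet_columns(panel, quartet)
    p1, p2, p3, p4 = cols
    term = (p1 - p2) * (p3 - p4)
    usable = np.isfinite(term)
    term = np.where(usable, term, 0.0)
    if panel.block_id is None:
        bid = np.zeros(panel.n_sites, dtype=np.int64)
    else:
        bid = panel.block_id
    n_blocks = int(bid.max()) + 1
    sums = np.bincount(bid, weights=term, minlength=n_blocks)
    counts = np.bincount(bid, weights=usable.astype(float), minlength=n_blocks)
    return np.column_stack([sums, counts])


def f4(panel: AlleleFrequencyPanel, quartet) -> float:
    """f4(A,B;C,D) = mean over usable sites of (pA-pB)(pC-pD)."""
    blocks = _f4_blocks(panel, quartet)
    n = blocks[:, 1].sum()
    if n == 0:
        return math.nan
    return float(blocks[:, 0].sum() / n)


def f2(panel: AlleleFrequencyPanel, a: str, b: str) -> float:
    """f2(A,B) = mean over usable sites of (pA-pB)^2."""
    pa, pb = panel.column(a), panel.column(b)
    term = (pa - pb) ** 2
    usable = np.isfinite(term)
    if not usable.any():
        return math.nan
    return float(term[usable].mean())


def f4_ratio(
    panel: AlleleFrequencyPanel,
    numerator_quartet,
    denominator_quartet,
    min_abs_denominator: float = 1e-9,
):
    """Admixture proportion alpha as a ratio of two f4 statistics.

    Returns (ratio, jackknife SE, stable flag).  The ratio is flagged
    unstable when |f4_den| falls below ``min_abs_denominator``.
    """
    num_b = _f4_blocks(panel, numerator_quartet)
    den_b = _f4_blocks(panel, denominator_quartet)
    n_num, n_den = num_b[:, 1].sum(), den_b[:, 1].sum()
    if n_num == 0 or n_den == 0 or den_b[:, 0].sum() == 0:
        return math.nan, math.nan, False
    # normalise to per-site means so the ratio of means is taken blockwise
    f4_den = den_b[:, 0].sum() / n_den
    stable = abs(f4_den) >= min_abs_denominator
    # ratio of sums equals ratio of means up to the shared site count when
    # the two quartets use the same usable-site masks; use mean-based blocks
    num_mb = np.column_stack([num_b[:, 0] / max(n_num, 1) * n_den, num_b[:, 1]])
    est, se = block_jackknife_ratio(num_mb, den_b)
    return est, se, stable


@dataclass
class F4Vector:
    """A vector of observed quartet statistics with jackknife covariance.

    ``entries`` pairs quartets with observed values; ``S`` is the
    block-jackknife covariance of the vector (symmetric PSD up to noise);
    ``statistic_kind`` is "D" or "f4".
    """

    entries: list[tuple[tuple[str, str, str, str], float]]
    S: np.ndarray
    statistic_kind: str

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        k = len(self.entries)
        if self.S.shape != (k, k):
            raise PanelError("covariance shape does not match entries")
        if not np.allclose(self.S, self.S.T, atol=1e-8):
            raise PanelError("covariance matrix not symmetric")

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.entries])

    @property
    def quartets(self) -> list[tuple[str, str, str, str]]:
        return [q for q, _ in self.entries]


def f4_vector(
    panel: AlleleFrequencyPanel,
    quartets,
    statistic: str = "D",
) -> F4Vector:
    """Observed D or f4 values for several quartets plus jackknife covariance.

    The covariance is the delete-one jackknife covariance of the vector,
    S = (g-1)/g * sum_j (v_j - vbar)(v_j - vbar)^T over blocks j, computed
    with equal block weighting.
    """
    if statistic not in ("D", "f4"):
        raise PanelError("statistic must be 'D' or 'f4'")
    if panel.block_id is None:
        raise PanelError("panel needs jackknife blocks for covariance")
    vals = []
    loo_rows = []
    for q in quartets:
        if statistic == "D":
            res = d_statistic(panel, q)
            pb = res.per_block
            tot_n, tot_d = pb[:, 0].sum(), pb[:, 1].sum()
            with np.errstate(divide="ignore", invalid="ignore"):
                loo = (tot_n - pb[:, 0]) / (tot_d - pb[:, 1])
            vals.append(res.D)
        else:
            fb = _f4_blocks(panel, q)
            tot_s, tot_c = fb[:, 0].sum(), fb[:, 1].sum()
            with np.errstate(divide="ignore", invalid="ignore"):
                loo = (tot_s - fb[:, 0]) / (tot_c - fb[:, 1])
            vals.append(tot_s / tot_c if tot_c > 0 else math.nan)
        loo_rows.append(loo)
    L = np.vstack(loo_rows).T  # blocks x quartets
    ok = np.all(np.isfinite(L), axis=1)
    L = L[ok]
    g = L.shape[0]
    if g < 2:
        raise PanelError("need >=2 usable blocks for covariance")
    centred = L - L.mean(axis=0)
    S = (g - 1) / g * (centred.T @ centred)
    return F4Vector(
        entries=[(tuple(q), float(v)) for q, v in zip(quartets, vals)],
        S=S,
        statistic_kind=statistic,
    )


# ------------------------------------------------------------------- sweep


def canonical_triplet(triplet) -> tuple[str, str, str]:
    """Deterministic (P1, P2, P3) orientation for an unordered triplet.

    P3 is the alphabetically smallest member, then P1 < P2 alphabetically.
    """
    s = sorted(triplet)
    p3, p1, p2 = s[0], s[1], s[2]
    return (p1, p2, p3)


def triplet_sweep(
    panel: AlleleFrequencyPanel,
    outgroup: str | None = None,
    z_threshold: float = 3.3,
    family_alpha: float = 0.05,
) -> pd.DataFrame:
    """D statistics for every ingroup triplet against a fixed outgroup.

    Rows follow the canonical triplet orientation; the table carries the
    raw two-sided normal p, a Bonferroni-adjusted significance flag at the
    stated family level, and the fixed-threshold flag |Z| > 3.3.  The two
    flags answer different multiple-testing conventions and are reported
    side by side.
    """
    outgroup = outgroup or panel.outgroup_id
    ingroup = [l for l in panel.lineage_ids if l != outgroup]
    if len(ingroup) < 3:
        raise PanelError("triplet sweep needs >=3 ingroup lineages")
    rows = []
    n_tests = math.comb(len(ingroup), 3)
    for trip in itertools.combinations(ingroup, 3):
        p1, p2, p3 = canonical_triplet(trip)
        res = d_statistic(panel, (p1, p2, p3, outgroup))
        p = res.p_value
        rows.append(
            {
                "P1": p1,
                "P2": p2,
                "P3": p3,
                "O": outgroup,
                "nsites": res.n_sites,
                "ABBA": res.abba_sum,
                "BABA": res.baba_sum,
                "D": res.D,
                "SE": res.se,
                "Z": res.Z,
                "p": p,
                "bonferroni_sig": bool(p * n_tests < family_alpha)
                if math.isfinite(p)
                else False,
                f"z{z_threshold}_sig": bool(abs(res.Z) > z_threshold)
                if math.isfinite(res.Z)
                else False,
            }
        )
    return pd.DataFrame(rows)
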