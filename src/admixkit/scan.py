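"""Windowed introgression scans: Dxy, fd, pi and permutation nulls.

A scan walks fixed windows along each chromosome and computes, per window,
absolute divergence Dxy between a donor and recipient lineage, the fd
admixture-fraction estimator for a (P1, P2, P3, O) quartet, and nucleotide
diversity pi.  Window values are tested against the genome-wide background
by resampling same-size site sets (the permutation null); candidate
introgressed blocks are maximal runs of windows with jointly low Dxy and
high fd.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd

from .dstats import site_patterns
from .panel import AlleleFrequencyPanel, PanelError, WindowIndex

__all__ = [
    "dxy_sites",
    "pi_sites",
    "fd_site_terms",
    "window_dxy",
    "window_fd",
    "window_pi",
    "permutation_test",
    "scan_windows",
    "detect_blocks",
]


# ------------------------------------------------------- per-site terms


def dxy_sites(panel: AlleleFrequencyPanel, a: str, b: str) -> np.ndarray:
    """Per-site Dxy term pA(1-pB) + pB(1-pA); NaN where either is missing."""
    pa, pb = panel.column(a), panel.column(b)
    return pa * (1.0 - pb) + pb * (1.0 - pa)


def pi_sites(panel: AlleleFrequencyPanel, lineage: str) -> np.ndarray:
    """Per-site nucleotide diversity 2k(n-k) / (n(n-1)) for one lineage."""
    j = panel.lineage_index(lineage)
    p = panel.freq[:, j]
    n = panel.called_n[:, j].astype(float)
    k = p * n
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * k * (n - k) / (n * (n - 1.0))
    pi[n < 2] = np.nan
    return pi


def fd_site_terms(panel: AlleleFrequencyPanel, quartet):
    """Per-site (abba - baba) numerator and donor-proxy denominator terms.

    The denominator replaces both P2 and P3 by the donor proxy
    PD = max(p2, p3) per site, the maximal-introgression reference of the
    fd estimator.  Requires a polarized panel (derived frequencies).
    """
    if not panel.polarized:
        raise PanelError("fd requires a polarized panel (derived frequencies)")
    p1, p2, p3, p4 = (panel.column(q) for q in quartet)
    abba, baba = site_patterns(p1, p2, p3, p4)
    pd_ = np.fmax(p2, p3)
    abba_d, baba_d = site_patterns(p1, pd_, pd_, p4)
    return abba - baba, abba_d - baba_d


# -------------------------------------------------------- window values


def _window_mean(values: np.ndarray, sites: np.ndarray) -> float:
    v = values[sites]
    v = v[np.isfinite(v)]
    return float(v.mean()) if v.size else math.nan


def window_dxy(panel, sites, a: str, b: str, denominator: str = "variant",
               window_bp: int | None = None) -> float:
    """Mean Dxy over a window's sites (or per-bp with ``denominator='bp'``)."""
    v = dxy_sites(panel, a, b)[sites]
    v = v[np.isfinite(v)]
    if v.size == 0:
        return math.nan
    if denominator == "bp":
        if not window_bp:
            raise PanelError("per-bp Dxy needs the window length")
        return float(v.sum() / window_bp)
    return float(v.mean())


def window_fd(panel, sites, quartet) -> float:
    """fd for one window; NaN (undefined) when the numerator is <= 0."""
    num_t, den_t = fd_site_terms(panel, quartet)
    ok = np.isfinite(num_t[sites]) & np.isfinite(den_t[sites])
    num = float(num_t[sites][ok].sum())
    den = float(den_t[sites][ok].sum())
    if num <= 0 or den == 0:
        return math.nan
    return num / den


def window_pi(panel, sites, lineage: str) -> float:
    """Mean per-site pi over a window (variant-only denominator)."""
    return _window_mean(pi_sites(panel, lineage), sites)


# ----------------------------------------------------------- permutation


def permutation_test(
    observed: float,
    site_num: np.ndarray,
    n_sites: int,
    n_perm: int,
    direction: str = "greater",
    seed=None,
    site_den: np.ndarray | None = None,
    exhaustive: bool = False,
):
    """Permutation p-value for a window statistic against the genome.

    The null recomputes the statistic on random same-size site sets drawn
    from the genome-wide pool: the statistic is mean(site_num) over the
    set, or sum(site_num)/sum(site_den) when ``site_den`` is given.  The
    p-value uses the add-one convention (1 + #as-or-more-extreme) /
    (1 + draws), so its floor is 1/(n_perm + 1).  ``exhaustive``
    enumerates every site subset instead of sampling (tiny inputs only).
    """
    if n_perm < 1 and not exhaustive:
        raise PanelError("n_perm must be >= 1")
    if direction not in ("greater", "less"):
        raise PanelError("direction must be 'greater' or 'less'")
    num = np.asarray(site_num, dtype=float)
    ok = np.isfinite(num) if site_den is None else (
        np.isfinite(num) & np.isfinite(site_den)
    )
    num = num[ok]
    den = None if site_den is None else np.asarray(site_den, float)[ok]
    pool = num.size
    if pool < 2 or pool < n_sites:
        return math.nan
    if not math.isfinite(observed):
        return math.nan

    def stat(idx) -> float:
        if den is None:
            return float(num[idx].mean())
        d = float(den[idx].sum())
        return float(num[idx].sum()) / d if d != 0 else math.nan

    if exhaustive:
        draws = np.array(
            [stat(list(c)) for c in itertools.combinations(range(pool), n_sites)]
        )
    else:
        rng = np.random.default_rng(seed)
        draws = np.empty(n_perm)
        for i in range(n_perm):
            draws[i] = stat(rng.choice(pool, size=n_sites, replace=False))
    draws = draws[np.isfinite(draws)]
    if direction == "greater":
        extreme = int(np.sum(draws >= observed))
    else:
        extreme = int(np.sum(draws <= observed))
    return (1 + extreme) / (1 + draws.size)


# ------------------------------------------------------------ scan driver


def scan_windows(
    panel: AlleleFrequencyPanel,
    windows: WindowIndex,
    dxy_pair: tuple[str, str],
    quartet=None,
    pi_lineages=(),
    n_perm: int = 0,
    seed=None,
) -> pd.DataFrame:
    """Per-window Dxy / fd / pi table with optional permutation p-values.

    Dxy is tested one-sided low (introgression lowers divergence between
    donor and recipient) and fd one-sided high.  Windows failing the
    missing-rate retention filter are kept in the table but flagged.
    """
    dxy_t = dxy_sites(panel, *dxy_pair)
    fd_terms = fd_site_terms(panel, quartet) if quartet is not None else None
    pi_terms = {l: pi_sites(panel, l) for l in pi_lineages}
    rng = np.random.default_rng(seed)

    rows = []
    for i, (c, s, e) in enumerate(windows.windows):
        sites = windows.site_membership[i]
        row = {
            "chrom": c,
            "start": s,
            "end": e,
            "nsites": len(sites),
            "retained": bool(windows.retained[i]),
            "dxy": window_dxy(panel, sites, *dxy_pair),
        }
        if fd_terms is not None:
            row["fd"] = window_fd(panel, sites, quartet)
        for l, t in pi_terms.items():
            row[f"pi_{l}"] = _window_mean(t, sites)
        if n_perm > 0:
            row["p_dxy"] = permutation_test(
                row["dxy"], dxy_t, len(sites), n_perm, "less",
                rng.integers(2**31),
            )
            if fd_terms is not None:
                row["p_fd"] = permutation_test(
                    row["fd"], fd_terms[0], len(sites), n_perm, "greater",
                    rng.integers(2**31), site_den=fd_terms[1],
                )
        rows.append(row)
    return pd.DataFrame(rows)


def detect_blocks(
    scan: pd.DataFrame,
    dxy_quantile: float = 0.25,
    fd_threshold: float = 0.5,
    min_run: int = 3,
    merge_gaps: int = 1,
) -> pd.DataFrame:
    """Candidate introgressed blocks from a window scan.

    A window qualifies when its Dxy falls below the given genome-wide
    quantile AND its fd exceeds ``fd_threshold`` (undefined fd fails).
    Maximal runs of >= ``min_run`` consecutive retained windows qualify as
    blocks; runs separated by at most ``merge_gaps`` failing windows are
    merged.  Blocks are returned as BED-like rows ranked by run length.
    """
    df = scan[scan["retained"]].reset_index(drop=True)
    if df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_windows"])
    dxy_cut = df["dxy"].quantile(dxy_quantile)
    passing = (df["dxy"] < dxy_cut) & (df["fd"] > fd_threshold)
    passing &= df["fd"].notna()

    blocks = []
    for chrom, sub in df.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        flags = passing[idx].to_numpy()
        runs = []  # (first, last) positions within idx
        start = None
        for k, f in enumerate(flags):
            if f and start is None:
                start = k
            elif not f and start is not None:
                runs.append((start, k - 1))
                start = None
        if start is not None:
            runs.append((start, len(flags) - 1))
        # merge runs across short gaps
        merged = []
        for r in runs:
            if merged and r[0] - merged[-1][1] - 1 <= merge_gaps:
                merged[-1] = (merged[-1][0], r[1])
            else:
                merged.append(r)
        for a, b in merged:
            n_win = b - a + 1
            if n_win < min_run:
                continue
            blocks.append(
                {
                    "chrom": chrom,
                    "start": int(sub.iloc[a]["start"]),
                    "end": int(sub.iloc[b]["end"]),
                    "n_windows": n_win,
                }
            )
    out = pd.DataFrame(blocks, columns=["chrom", "start", "end", "n_windows"])
    return out.sort_values("n_windows", ascending=False, ignore_index=True)


def blocks_to_bed(blocks: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for i, row in blocks.iterrows():
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\tblock{i}\t"
                f"{row.n_windows}\t.\n"
            )
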