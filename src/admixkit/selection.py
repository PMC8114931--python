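"""Counting-based pairwise dN/dS (Nei--Gojobori 1986) and the
foreground-versus-background permutation comparison.

Expected synonymous and nonsynonymous site counts come from enumerating
all nine single-base changes of each codon under the standard genetic
code (changes to stop codons count as nonsynonymous, which keeps the
site-count conservation S + N = 3 * codons exact); observed differences
in multi-difference codons are averaged over all minimal mutational paths
that avoid stop codons.  Proportions are Jukes--Cantor corrected,
d = -(3/4) ln(1 - 4p/3), and omega = dN/dS.

The downstream test asks whether genes in introgressed genomic regions
(foreground) evolve under different constraint than genes concordant
with the consensus phylogeny (background), by permuting gene class
labels.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .simulate import _CODON_TABLE

__all__ = [
    "CodonAlignment",
    "OmegaResult",
    "ng86_pairwise",
    "foreground_background_test",
    "read_codon_fasta",
]

_VALID = set("ACGT")


@dataclass
class CodonAlignment:
    """A gene's aligned coding sequences with a foreground/background label."""

    gene_id: str
    seqs: list[str]
    class_label: str | None = None  # "fg" or "bg"

    def __post_init__(self) -> None:
        lens = {len(s) for s in self.seqs}
        if len(lens) != 1:
            raise ValueError(f"{self.gene_id}: unequal sequence lengths")
        if lens.pop() % 3 != 0:
            raise ValueError(f"{self.gene_id}: length not divisible by 3")


@dataclass
class OmegaResult:
    """NG86 estimates for one sequence pair."""

    gene_id: str
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    dS: float
    dN: float
    omega: float          # NaN when dS == 0 or a correction is undefined
    n_codons: int         # ungapped codon columns used

    @property
    def defined(self) -> bool:
        return math.isfinite(self.omega)


# -------------------------------------------------------- codon counting


def _syn_fraction(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon."""
    aa = _CODON_TABLE[codon]
    syn = 0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            cand = codon[:pos] + alt + codon[pos + 1 :]
            if _CODON_TABLE[cand] == aa:
                syn += 1
    s = syn / 3.0
    return s, 3.0 - s


def _path_counts(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) between two codons, averaged over stop-free minimal paths."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        valid = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _CODON_TABLE[nxt] == "*":
                valid = False
                break
            if _CODON_TABLE[nxt] == _CODON_TABLE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if valid:
            paths.append((sd, nd))
    if not paths:  # every path crosses a stop; fall back to all paths
        for order in itertools.permutations(diff):
            cur = c1
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if _CODON_TABLE.get(nxt, "*") == _CODON_TABLE.get(cur, "*"):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jc_correct(p: float) -> float:
    if p == 0.0:
        return 0.0
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_pairwise(seq_a: str, seq_b: str, gene_id: str = "gene") -> OmegaResult:
    """NG86 dN/dS for one aligned coding sequence pair.

    Codons containing gaps or ambiguity codes in either sequence are
    dropped pairwise; an internal stop codon raises.  ``omega`` is NaN
    (flagged undefined) when dS = 0 or the Jukes--Cantor correction is
    undefined (p >= 3/4).
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    if len(seq_a) % 3 != 0:
        raise ValueError("alignment length must be divisible by 3")

    S = N = Sd = Nd = 0.0
    used = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if not (set(ca) <= _VALID and set(cb) <= _VALID):
            continue  # gap/ambiguity: dropped pairwise
        if _CODON_TABLE[ca] == "*" or _CODON_TABLE[cb] == "*":
            raise ValueError(f"{gene_id}: internal stop codon at position {i}")
        sa, na = _syn_fraction(ca)
        sb, nb = _syn_fraction(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _path_counts(ca, cb)
        Sd += sd
        Nd += nd
        used += 1

    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS, dN = _jc_correct(pS), _jc_correct(pN)
    if not math.isfinite(dS) or not math.isfinite(dN) or dS == 0.0:
        omega = math.nan
    else:
        omega = dN / dS
    return OmegaResult(
        gene_id=gene_id, S_sites=S, N_sites=N, Sd=Sd, Nd=Nd,
        dS=dS, dN=dN, omega=omega, n_codons=used,
    )


# ------------------------------------------------------ permutation test


def foreground_background_test(
    omegas_fg,
    omegas_bg,
    n_perm: int = 1000,
    seed=None,
    alternative: str = "greater",
    use_median: bool = False,
    exhaustive: bool = False,
):
    """Permutation test of gene-level omega between fore- and background.

    The statistic is mean(fg) - mean(bg) (or medians); the null shuffles
    gene class labels.  One-sided by default in the direction fg > bg
    (the adaptive-introgression hypothesis); ``alternative`` may be
    'greater', 'less' or 'two-sided'.  Undefined omegas are excluded and
    counted.  Returns a dict with the group means, the p-value (add-one
    convention) and exclusion counts.
    """
    fg = np.asarray(omegas_fg, dtype=float)
    bg = np.asarray(omegas_bg, dtype=float)
    n_excl_fg = int(np.sum(~np.isfinite(fg)))
    n_excl_bg = int(np.sum(~np.isfinite(bg)))
    fg, bg = fg[np.isfinite(fg)], bg[np.isfinite(bg)]
    if len(fg) == 0 or len(bg) == 0:
        raise ValueError("a group is empty after excluding undefined omegas")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError("alternative must be greater, less or two-sided")
    loc = np.median if use_median else np.mean

    obs = float(loc(fg) - loc(bg))
    pooled = np.concatenate([fg, bg])
    n_fg = len(fg)

    def extreme(delta: float) -> bool:
        if alternative == "greater":
            return delta >= obs
        if alternative == "less":
            return delta <= obs
        return abs(delta) >= abs(obs)

    count = 0
    if exhaustive:
        draws = 0
        for idx in itertools.combinations(range(len(pooled)), n_fg):
            mask = np.zeros(len(pooled), dtype=bool)
            mask[list(idx)] = True
            if extreme(float(loc(pooled[mask]) - loc(pooled[~mask]))):
                count += 1
            draws += 1
    else:
        rng = np.random.default_rng(seed)
        draws = n_perm
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if extreme(float(loc(perm[:n_fg]) - loc(perm[n_fg:]))):
                count += 1
    p = (1 + count) / (1 + draws)
    return {
        "mean_fg": float(loc(fg)),
        "mean_bg": float(loc(bg)),
        "statistic": obs,
        "p": p,
        "n_fg": len(fg),
        "n_bg": len(bg),
        "n_excluded_fg": n_excl_fg,
        "n_excluded_bg": n_excl_bg,
        "alternative": alternative,
        "n_draws": draws,
    }


# ------------------------------------------------------------------- I/O


def read_codon_fasta(path, gene_id: str | None = None,
                     class_label: str | None = None) -> CodonAlignment:
    """Read one gene's codon alignment from a FASTA file."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise ValueError(f"{path}: need >= 2 aligned sequences")
    return CodonAlignment(
        gene_id=gene_id or str(path),
        seqs=[str(r.seq).upper() for r in records],
        class_label=class_label,
    )


def read_class_table(path) -> dict[str, str]:
    """Read a ``gene_id<TAB>fg|bg`` class table."""
    classes: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1] not in ("fg", "bg"):
                raise ValueError(f"class table line {ln}: expected 'gene<TAB>fg|bg'")
            classes[parts[0]] = parts[1]
    return classes
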