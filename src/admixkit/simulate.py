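"""Synthetic data with known ground truth for every pipeline stage.

Allele frequencies drift down a user-specified admixture graph under a
Balding--Nichols (Beta) model: along an edge with drift d the child
frequency is Beta-distributed with mean p (the parent frequency) and
variance d * p * (1 - p); at an admixture node the frequency is the
deterministic mixture alpha * p1 + (1 - alpha) * p2.  Because mixing is
deterministic and edge increments independent, leaf-frequency covariances
— and hence every expected f-statistic — follow exactly from the graph by
a moment recursion (:func:`expected_leaf_covariance`), which the tests use
as the analytic oracle.

The other generators plant introgressed haplotype blocks in windowed
panels, draw triplet internal branch lengths from exponential /
shifted-exponential mixtures, and evolve codon alignment pairs with a
controlled dN/dS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graph import AdmixtureGraph, GraphError
from .panel import AlleleFrequencyPanel

__all__ = [
    "SimulationConfig",
    "simulate_frequencies",
    "simulate_scan_panel",
    "simulate_triplet_lengths",
    "simulate_codon_pair",
    "expected_leaf_covariance",
    "expected_f4_generative",
    "panel_to_vcf",
]


@dataclass
class SimulationConfig:
    """Study conditions for one frequency simulation.

    ``root_freq_law`` is ("uniform", lo, hi) for the ancestral frequency;
    ``drift_model`` is "beta" (Balding--Nichols, exact mean/variance) or
    "gaussian" (normal increments truncated to [0, 1]).  Monomorphic-at-
    all-leaves sites are dropped post hoc unless ``keep_monomorphic``, as
    a real SNV panel would drop them; the truth record reports the
    retention fraction.
    """

    graph: AdmixtureGraph
    n_sites: int
    seed: int
    outgroup: str | None = None
    root_freq_law: tuple = ("uniform", 0.05, 0.95)
    drift_model: str = "beta"
    chrom: str = "chr1"
    spacing: int = 100
    called_copies: int = 20
    keep_monomorphic: bool = False


def _draw_root(law, n, rng):
    kind = law[0]
    if kind == "uniform":
        return rng.uniform(law[1], law[2], size=n)
    if kind == "beta":
        return rng.beta(law[1], law[2], size=n)
    raise ValueError(f"unknown root_freq_law {law!r}")


def _drift(p: np.ndarray, d: float, model: str, rng, edge) -> np.ndarray:
    """One edge of frequency drift with mean p and variance d*p*(1-p)."""
    if d == 0.0:
        return p.copy()
    if model == "beta":
        scale = (1.0 - d) / d
        if scale <= 0:
            raise GraphError(f"drift on edge {edge} implies Beta shape <= 0")
        a = p * scale
        b = (1.0 - p) * scale
        out = p.copy()
        interior = (p > 0.0) & (p < 1.0)
        out[interior] = rng.beta(a[interior], b[interior])
        return out
    if model == "gaussian":
        sd = np.sqrt(d * p * (1.0 - p))
        return np.clip(p + rng.normal(0.0, 1.0, size=p.shape) * sd, 0.0, 1.0)
    raise ValueError(f"unknown drift_model {model!r}")


def _node_frequencies(cfg: SimulationConfig, rng) -> dict[str, np.ndarray]:
    graph = cfg.graph
    freqs: dict[str, np.ndarray] = {
        graph.root: _draw_root(cfg.root_freq_law, cfg.n_sites, rng)
    }
    pending = set(graph.nodes) - {graph.root}
    while pending:
        progressed = False
        for node in sorted(pending):
            parents = graph._parents[node]
            if any(p not in freqs for p in parents):
                continue
            if node in graph.admixture:
                p1, p2, a = graph.admixture[node]
                mixed = a * freqs[p1] + (1.0 - a) * freqs[p2]
                d1 = graph.edges[(p1, node)]
                d2 = graph.edges[(p2, node)]
                extra = max(d1, d2)  # admixture edges usually carry 0 drift
                freqs[node] = (
                    _drift(mixed, extra, cfg.drift_model, rng, (p1, node))
                    if extra > 0
                    else mixed
                )
            else:
                parent = parents[0]
                freqs[node] = _drift(
                    freqs[parent],
                    graph.edges[(parent, node)],
                    cfg.drift_model,
                    rng,
                    (parent, node),
                )
            pending.discard(node)
            progressed = True
        if not progressed:  # pragma: no cover - guarded by graph validation
            raise GraphError("graph is not traversable from the root")
    return freqs


def simulate_frequencies(cfg: SimulationConfig):
    """Simulate an :class:`AlleleFrequencyPanel` under an admixture graph.

    Returns (panel, truth) where truth records the generating parameters
    and the post-ascertainment retention fraction.  The same config and
    seed always reproduce the same panel bitwise.
    """
    if cfg.n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    node_freqs = _node_frequencies(cfg, rng)
    leaves = cfg.graph.leaves
    freq = np.column_stack([node_freqs[l] for l in leaves])

    keep = np.ones(cfg.n_sites, dtype=bool)
    if not cfg.keep_monomorphic:
        keep = ~(np.all(freq == 0.0, axis=1) | np.all(freq == 1.0, axis=1))
    freq = freq[keep]
    n_kept = freq.shape[0]

    outgroup = cfg.outgroup or leaves[-1]
    panel = AlleleFrequencyPanel(
        lineage_ids=list(leaves),
        chrom=np.repeat(cfg.chrom, n_kept),
        pos=(np.flatnonzero(keep) + 1) * cfg.spacing,
        freq=freq,
        called_n=np.full((n_kept, len(leaves)), cfg.called_copies),
        outgroup_id=outgroup,
        polarized=True,
    )
    truth = {
        "edges": {f"{p}->{c}": d for (p, c), d in cfg.graph.edges.items()},
        "alphas": {n: a for n, (_, _, a) in cfg.graph.admixture.items()},
        "n_sites": cfg.n_sites,
        "retained_fraction": n_kept / cfg.n_sites,
        "seed": cfg.seed,
    }
    return panel, truth


def simulate_scan_panel(
    cfg: SimulationConfig,
    block: tuple[str, int, int],
    donor: str,
    recipient: str,
    block_drift: float = 0.002,
):
    """Panel with a planted introgressed haplotype block.

    Outside ``block`` (0-based half-open) the recipient evolves on its own
    graph branch; inside it, recipient frequencies are copied from the
    donor with a small extra Beta drift, producing locally low
    Dxy(donor, recipient) and a strong ABBA excess (high fd).  Returns
    (panel, truth) where truth carries the planted interval as a BED-like
    tuple.
    """
    if donor == recipient:
        raise ValueError("donor and recipient must differ")
    panel, truth = simulate_frequencies(cfg)
    bc, bs, be = block
    rng = np.random.default_rng(np.random.default_rng(cfg.seed).integers(2**31))
    in_block = (panel.chrom == bc) & (panel.pos - 1 >= bs) & (panel.pos - 1 < be)
    if in_block.any():
        di = panel.lineage_index(donor)
        ri = panel.lineage_index(recipient)
        donor_f = panel.freq[in_block, di]
        panel.freq[in_block, ri] = _drift(
            donor_f, block_drift, cfg.drift_model, rng, ("donor", recipient)
        )
    truth = dict(truth)
    truth["block"] = (bc, int(bs), int(be))
    truth["donor"], truth["recipient"] = donor, recipient
    return panel, truth


def simulate_triplet_lengths(pi2: float, C: float, lam: float, n: int, seed: int):
    """Triplet internal branch lengths from an exponential mixture.

    Each draw is Exp(lam) with probability 1 - pi2 and C + Exp(lam)
    otherwise — the ILS-only null versus the introgression/speciation
    shifted component.  Returns (lengths, truth).
    """
    if not 0.0 <= pi2 <= 1.0:
        raise ValueError("pi2 must lie in [0, 1]")
    if C < 0 or lam <= 0:
        raise ValueError("need C >= 0 and lam > 0")
    rng = np.random.default_rng(seed)
    shifted = rng.random(n) < pi2
    x = rng.exponential(1.0 / lam, size=n)
    x[shifted] += C
    return x, {"pi2": pi2, "C": C, "lam": lam, "n": n, "seed": seed}


# ---------------------------------------------------------------- codons

_BASES = "TCAG"
_CODON_TABLE = {}
_aa = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _a in enumerate(_aa):
    _CODON_TABLE[_BASES[_i // 16] + _BASES[(_i // 4) % 4] + _BASES[_i % 4]] = _a
SENSE_CODONS = sorted(c for c, a in _CODON_TABLE.items() if a != "*")


def simulate_codon_pair(omega: float, t: float, n_codons: int, seed: int):
    """Evolve a codon alignment pair with a controlled dN/dS.

    The ancestor is drawn uniformly from sense codons; mutations are
    proposed at Poisson(3 * n_codons * t) random positions, changes to
    stop codons are rejected, synonymous changes accepted with rate 1 and
    nonsynonymous with relative rate ``omega``.  Returns (seq_ancestor,
    seq_descendant, truth).
    """
    if omega < 0 or t < 0:
        raise ValueError("need omega >= 0 and t >= 0")
    rng = np.random.default_rng(seed)
    codons = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n_codons)]
    anc = "".join(codons)
    desc = list(anc)
    n_events = rng.poisson(3 * n_codons * t)
    for _ in range(n_events):
        site = int(rng.integers(3 * n_codons))
        ci, off = divmod(site, 3)
        codon = "".join(desc[3 * ci : 3 * ci + 3])
        base = desc[site]
        new = _BASES[int(rng.integers(4))]
        if new == base:
            continue
        cand = codon[:off] + new + codon[off + 1 :]
        if _CODON_TABLE[cand] == "*":
            continue
        synonymous = _CODON_TABLE[cand] == _CODON_TABLE[codon]
        if synonymous or rng.random() < omega:
            desc[site] = new
    truth = {"omega": omega, "t": t, "n_codons": n_codons, "seed": seed}
    return anc, "".join(desc), truth


# ------------------------------------------------------- analytic oracle


def expected_leaf_covariance(graph: AdmixtureGraph, root_mean: float, root_var: float):
    """Exact node-frequency covariance matrix under the Beta-drift model.

    With deterministic admixture mixing, every node frequency is linear in
    the root frequency and the per-edge increments, so covariances follow
    a moment recursion in topological order: a drift edge adds variance
    d * (mu - E[p^2]) at its start, and an admixture node mixes rows of
    the covariance matrix linearly.  Returns (node order, covariance).
    """
    order: list[str] = []
    pending = set(graph.nodes)
    cov: dict[tuple[str, str], float] = {}
    var_done: dict[str, float] = {}

    def second_moment(node: str) -> float:
        return var_done[node] + root_mean**2

    # process root first, then nodes whose parents are done
    var_done[graph.root] = root_var
    order.append(graph.root)
    pending.discard(graph.root)
    cov[(graph.root, graph.root)] = root_var
    while pending:
        for node in sorted(pending):
            parents = graph._parents[node]
            if any(p not in var_done for p in parents):
                continue
            if node in graph.admixture:
                p1, p2, a = graph.admixture[node]
                for other in order:
                    cov[(node, other)] = cov[(other, node)] = (
                        a * cov[tuple(sorted((p1, other)))]
                        + (1 - a) * cov[tuple(sorted((p2, other)))]
                    )
                base_var = (
                    a**2 * var_done[p1]
                    + (1 - a) ** 2 * var_done[p2]
                    + 2 * a * (1 - a) * cov[tuple(sorted((p1, p2)))]
                )
                d = max(graph.edges[(p1, node)], graph.edges[(p2, node)])
                het = root_mean - (base_var + root_mean**2)
                var_done[node] = base_var + d * het
            else:
                parent = parents[0]
                d = graph.edges[(parent, node)]
                for other in order:
                    cov[(node, other)] = cov[(other, node)] = cov[
                        tuple(sorted((parent, other)))
                    ]
                het = root_mean - second_moment(parent)
                var_done[node] = var_done[parent] + d * het
            cov[(node, node)] = var_done[node]
            order.append(node)
            pending.discard(node)
            break
        else:  # pragma: no cover
            raise GraphError("graph is not traversable")
    leaves = graph.leaves
    M = np.array(
        [[cov[tuple(sorted((a, b)))] for b in leaves] for a in leaves]
    )
    return leaves, M


def expected_f4_generative(
    graph: AdmixtureGraph,
    quartet,
    root_mean: float = 0.5,
    root_var: float = 0.0675,
):
    """Exact E[f4] under the Beta-drift generative model (no ascertainment).

    Defaults match the Uniform(0.05, 0.95) root law.  This is the
    simulation-side counterpart of :func:`admixkit.graph.expected_f4`,
    which works in free drift units.
    """
    leaves, M = expected_leaf_covariance(graph, root_mean, root_var)
    ix = {l: i for i, l in enumerate(leaves)}
    a, b, c, d = (ix[x] for x in quartet)
    return float(M[a, c] - M[a, d] - M[b, c] + M[b, d])


# ------------------------------------------------------------ VCF export


def panel_to_vcf(
    panel: AlleleFrequencyPanel, path, individuals_per_lineage: int = 5
) -> dict[str, str]:
    """Write the panel as a diploid VCF plus implied popmap.

    Each lineage becomes ``individuals_per_lineage`` diploid samples whose
    genotypes carry round(freq * 2m) derived copies, so re-reading the VCF
    recovers the frequencies up to that rounding grid.  Returns the
    sample -> lineage map (write it with :func:`write_popmap`).
    """
    m = individuals_per_lineage
    samples = [f"{lin}_{i}" for lin in panel.lineage_ids for i in range(m)]
    popmap = {f"{lin}_{i}": lin for lin in panel.lineage_ids for i in range(m)}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(panel.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for s in range(panel.n_sites):
            gts = []
            for j in range(panel.n_lineages):
                f = panel.freq[s, j]
                if math.isnan(f):
                    gts.extend(["./."] * m)
                    continue
                k = int(round(f * 2 * m))
                alleles = [1] * k + [0] * (2 * m - k)
                gts.extend(f"{alleles[2*i]}/{alleles[2*i+1]}" for i in range(m))
            fh.write(
                f"{panel.chrom[s]}\t{panel.pos[s]}\t.\tA\tT\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
    return popmap


def write_popmap(popmap: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sample, lineage in popmap.items():
            fh.write(f"{sample}\t{lineage}\n")
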