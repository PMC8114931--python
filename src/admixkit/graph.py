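"""Admixture graphs: expected f-statistics and scenario fitting.

An admixture graph is a rooted DAG whose edges carry drift lengths (in f2
units) and whose admixture nodes (two parents) carry a mixing proportion
``alpha`` attached to the first parent edge.  Under the linear-drift model
a leaf's allele frequency is the root frequency plus independent edge
increments weighted by the probability ``w_i(e)`` that a lineage sampled
at leaf i traverses edge e on its way to the root, so

    E[f4(A,B;C,D)] = sum_e d_e (w_A(e)-w_B(e)) (w_C(e)-w_D(e)).

Competing reticulation scenarios are fitted to an observed statistic
vector by minimising the Mahalanobis cost

    (F - f)^T S^{-1} (F - f)

over drifts and mixing proportions with Nelder--Mead, where F are model
expectations, f the observations and S their block-jackknife covariance;
scenarios are then ranked by minimal error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, nnls
from scipy.special import expit, logit

from .dstats import F4Vector

__all__ = [
    "AdmixtureGraph",
    "GraphError",
    "leaf_edge_weights",
    "expected_f4",
    "expected_f2",
    "ScenarioModel",
    "ScenarioResults",
    "fit_scenario",
    "compare_scenarios",
]


class GraphError(ValueError):
    """Raised for structurally invalid admixture graphs."""


@dataclass
class AdmixtureGraph:
    """Rooted DAG with drift lengths and admixture proportions.

    ``edges`` maps (parent, child) to drift length d_e >= 0; ``admixture``
    maps an admixture node to (parent1, parent2, alpha) with alpha the
    probability of tracing through parent1.  Leaves are nodes without
    children; every non-root node has one parent (tree node) or two
    (admixture node).
    """

    edges: dict[tuple[str, str], float]
    admixture: dict[str, tuple[str, str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()

    # -------------------------------------------------------- structure

    def _validate(self) -> None:
        parents: dict[str, list[str]] = {}
        children: dict[str, list[str]] = {}
        for (p, c), d in self.edges.items():
            if d < 0:
                raise GraphError(f"negative drift on edge {p}->{c}")
            parents.setdefault(c, []).append(p)
            children.setdefault(p, []).append(c)
        nodes = set(parents) | set(children)
        roots = [n for n in nodes if n not in parents]
        if len(roots) != 1:
            raise GraphError(f"graph must have exactly one root, found {roots}")
        self._root = roots[0]
        for n, ps in parents.items():
            if len(ps) == 1:
                if n in self.admixture:
                    raise GraphError(f"admixture node {n} has one parent edge")
            elif len(ps) == 2:
                if n not in self.admixture:
                    raise GraphError(f"two-parent node {n} lacks an alpha")
                p1, p2, a = self.admixture[n]
                if {p1, p2} != set(ps):
                    raise GraphError(f"admixture parents of {n} mismatch edges")
                if not 0.0 <= a <= 1.0:
                    raise GraphError(f"alpha of {n} outside [0, 1]")
            else:
                raise GraphError(f"node {n} has {len(ps)} parents")
        # acyclicity via iterative DFS
        state: dict[str, int] = {}
        order: list[str] = []

        def visit(u: str) -> None:
            stack = [(u, iter(children.get(u, [])))]
            state[u] = 1
            while stack:
                node, it = stack[-1]
                advanced = False
                for v in it:
                    if state.get(v, 0) == 1:
                        raise GraphError("graph contains a cycle")
                    if state.get(v, 0) == 0:
                        state[v] = 1
                        stack.append((v, iter(children.get(v, []))))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 2
                    order.append(node)
                    stack.pop()

        visit(self._root)
        if set(state) != nodes:
            raise GraphError("graph is disconnected from the root")
        self._parents = parents
        self._children = children
        self._nodes = nodes

    @property
    def root(self) -> str:
        return self._root

    @property
    def nodes(self) -> set[str]:
        return set(self._nodes)

    @property
    def leaves(self) -> list[str]:
        return sorted(n for n in self._nodes if n not in self._children)

    @property
    def edge_list(self) -> list[tuple[str, str]]:
        return sorted(self.edges)

    @property
    def n_admixture(self) -> int:
        return len(self.admixture)

    def with_params(
        self,
        drifts: dict[tuple[str, str], float] | None = None,
        alphas: dict[str, float] | None = None,
    ) -> "AdmixtureGraph":
        edges = dict(self.edges)
        if drifts:
            edges.update(drifts)
        admix = dict(self.admixture)
        if alphas:
            for node, a in alphas.items():
                p1, p2, _ = admix[node]
                admix[node] = (p1, p2, a)
        return AdmixtureGraph(edges=edges, admixture=admix)

    # ---------------------------------------------------------- file I/O

    @classmethod
    def from_file(cls, path) -> "AdmixtureGraph":
        """Parse the text DAG format.

        One line per tree edge ``parent child drift`` and one
        ``admix child parent1 parent2 alpha`` line per admixture node
        (its two incoming edges default to drift 0 unless also listed).
        """
        edges: dict[tuple[str, str], float] = {}
        admix: dict[str, tuple[str, str, float]] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.split("#")[0].strip()
                if not line:
                    continue
                parts = line.split()
                if parts[0] == "admix":
                    if len(parts) != 5:
                        raise GraphError(f"line {ln}: admix needs 4 fields")
                    _, child, p1, p2, a = parts
                    admix[child] = (p1, p2, float(a))
                    edges.setdefault((p1, child), 0.0)
                    edges.setdefault((p2, child), 0.0)
                elif len(parts) == 3:
                    p, c, d = parts
                    edges[(p, c)] = float(d)
                else:
                    raise GraphError(f"line {ln}: expected 'parent child drift'")
        return cls(edges=edges, admixture=admix)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for (p, c) in self.edge_list:
                if c in self.admixture:
                    continue
                fh.write(f"{p} {c} {self.edges[(p, c)]:.8g}\n")
            for child, (p1, p2, a) in sorted(self.admixture.items()):
                fh.write(f"admix {child} {p1} {p2} {a:.6g}\n")
                for p in (p1, p2):
                    if self.edges[(p, child)] != 0.0:
                        fh.write(f"{p} {child} {self.edges[(p, child)]:.8g}\n")

    # ------------------------------------------------------ path algebra

    def root_paths(self, leaf: str) -> list[tuple[float, frozenset]]:
        """All rootward paths from a leaf as (probability, edge set) pairs."""
        if leaf not in self._nodes:
            raise GraphError(f"unknown node {leaf!r}")

        def up(node: str) -> list[tuple[float, frozenset]]:
            if node == self._root:
                return [(1.0, frozenset())]
            out = []
            for parent in self._parents[node]:
                if node in self.admixture:
                    p1, p2, a = self.admixture[node]
                    prob = a if parent == p1 else 1.0 - a
                else:
                    prob = 1.0
                for pr, es in up(parent):
                    out.append((prob * pr, es | {(parent, node)}))
            return out

        return up(leaf)


def leaf_edge_weights(graph: AdmixtureGraph) -> dict[str, dict[tuple[str, str], float]]:
    """Per-leaf traversal probabilities w_i(e) for every edge.

    ``w[leaf][edge]`` is the probability that a lineage sampled at the leaf
    passes through the edge while tracing back to the root, multiplying
    alpha (first parent) or 1-alpha (second parent) at each admixture node.
    """
    weights: dict[str, dict[tuple[str, str], float]] = {}
    for leaf in graph.leaves:
        w = {e: 0.0 for e in graph.edges}
        for prob, es in graph.root_paths(leaf):
            for e in es:
                w[e] += prob
        weights[leaf] = w
    return weights


def expected_f4(graph: AdmixtureGraph, quartet) -> float:
    """Model-expected f4(A,B;C,D) = sum_e d_e (wA-wB)(wC-wD)."""
    a, b, c, d = quartet
    w = leaf_edge_weights(graph)
    for x in quartet:
        if x not in w:
            raise GraphError(f"unknown leaf {x!r}")
    return float(
        sum(
            graph.edges[e] * (w[a][e] - w[b][e]) * (w[c][e] - w[d][e])
            for e in graph.edges
        )
    )


def expected_f2(graph: AdmixtureGraph, a: str, b: str) -> float:
    """Model-expected f2(A,B) = expected_f4(A,B;A,B)."""
    return expected_f4(graph, (a, b, a, b))


# --------------------------------------------------------------- fitting


class _FStatDesign:
    """Fast evaluation of the (n_quartets, n_edges) coefficient matrix.

    The expected statistic vector is F = C(alpha) @ d with C built from the
    per-leaf edge-traversal probabilities; the root paths of every leaf are
    enumerated once, so evaluating C for a new alpha vector is a handful of
    numpy products.
    """

    def __init__(self, graph: AdmixtureGraph, quartets) -> None:
        self.edge_order = graph.edge_list
        self.admix_nodes = sorted(graph.admixture)
        edge_ix = {e: j for j, e in enumerate(self.edge_order)}
        admix_ix = {n: i for i, n in enumerate(self.admix_nodes)}
        self.quartets = [tuple(q) for q in quartets]
        leaves = sorted({x for q in self.quartets for x in q})
        for leaf in leaves:
            if leaf not in graph.leaves:
                raise GraphError(f"quartet leaf {leaf!r} not in graph")
        self.leaf_ix = {l: i for i, l in enumerate(leaves)}
        # per leaf: indicator matrix of path edges + admixture factor specs
        self._paths = []
        for leaf in leaves:
            paths = graph.root_paths(leaf)
            ind = np.zeros((len(paths), len(self.edge_order)))
            firsts, seconds = [], []
            for k, (_, es) in enumerate(paths):
                f1, f2 = [], []
                for e in es:
                    ind[k, edge_ix[e]] = 1.0
                    child = e[1]
                    if child in graph.admixture:
                        p1, p2, _ = graph.admixture[child]
                        (f1 if e[0] == p1 else f2).append(admix_ix[child])
                firsts.append(np.array(f1, dtype=int))
                seconds.append(np.array(f2, dtype=int))
            self._paths.append((ind, firsts, seconds))

    def weights(self, alpha_vec: np.ndarray) -> np.ndarray:
        """(n_leaves, n_edges) traversal-probability matrix for one alpha."""
        W = np.empty((len(self._paths), len(self.edge_order)))
        for i, (ind, firsts, seconds) in enumerate(self._paths):
            probs = np.array(
                [
                    float(np.prod(alpha_vec[f]) * np.prod(1.0 - alpha_vec[s]))
                    for f, s in zip(firsts, seconds)
                ]
            )
            W[i] = probs @ ind
        return W

    def coefs(self, alpha_vec: np.ndarray) -> np.ndarray:
        W = self.weights(np.asarray(alpha_vec, dtype=float))
        ix = self.leaf_ix
        C = np.empty((len(self.quartets), len(self.edge_order)))
        for i, (a, b, c, d) in enumerate(self.quartets):
            C[i] = (W[ix[a]] - W[ix[b]]) * (W[ix[c]] - W[ix[d]])
        return C


@dataclass
class ScenarioResults:
    """Fitted admixture-graph scenario: estimates, cost and diagnostics."""

    scenario_id: str
    graph: AdmixtureGraph
    drifts: dict[tuple[str, str], float]
    alphas: dict[str, float]
    scale: float
    minimal_error: float
    n_restarts: int
    converged: bool
    statistic_kind: str
    fused_root_edges: tuple[tuple[str, str], ...] | None = None

    @property
    def fitted_graph(self) -> AdmixtureGraph:
        return self.graph.with_params(drifts=self.drifts, alphas=self.alphas)

    def predicted(self, quartets) -> np.ndarray:
        g = self.fitted_graph
        return self.scale * np.array([expected_f4(g, q) for q in quartets])

    def summary(self) -> str:
        lines = [
            f"Admixture-graph scenario fit: {self.scenario_id}",
            f"  statistic fitted : {self.statistic_kind}",
            f"  minimal error    : {self.minimal_error:.6g}",
            f"  restarts         : {self.n_restarts}"
            f"   converged: {self.converged}",
            f"  admixture edges  : {self.graph.n_admixture}",
        ]
        if self.statistic_kind == "D":
            lines.append(f"  fitted scale     : {self.scale:.6g}")
        for node, a in sorted(self.alphas.items()):
            lines.append(f"  alpha[{node}]     : {a:.4f}")
        if self.fused_root_edges:
            e1, e2 = self.fused_root_edges
            s = self.drifts[e1] + self.drifts[e2]
            lines.append(
                f"  root-pair drift  : {s:.6g} (edges {e1} + {e2}, fused)"
            )
        for e in sorted(self.drifts):
            lines.append(f"  drift[{e[0]}->{e[1]}] : {self.drifts[e]:.6g}")
        return "\n".join(lines)


class ScenarioModel:
    """Fit one admixture-graph topology to an observed statistic vector.

    The cost (F - f)^T S^{-1} (F - f) is minimised by a combination of
    linear algebra and Nelder--Mead: for a candidate alpha vector the
    expectations are linear in the drift lengths, F = C(alpha) @ d, so the
    optimal nonnegative d is a whitened non-negative least-squares solve;
    Nelder--Mead (multi-restart) searches only over the admixture
    proportions, mapped through a logistic transform.

    Parameters
    ----------
    graph : AdmixtureGraph
        The scenario topology; its alpha values serve as an
        initialisation hint.
    observed : F4Vector
        Observed D or f4 values with their covariance S.  For D statistics
        the drift estimates absorb one overall positive scale, since D's
        quartet-specific denominator is not predicted by the drift algebra;
        only products scale * d_e are meaningful there.
    fit_admixture_edge_drifts : bool
        Whether the two edges entering each admixture node carry free drift
        (default False: fixed at 0, the usual graph convention).
    ridge : float
        Added to the diagonal of S before (pseudo-)inversion.
    """

    def __init__(
        self,
        graph: AdmixtureGraph,
        observed: F4Vector,
        scenario_id: str = "scenario",
        fit_admixture_edge_drifts: bool = False,
        ridge: float = 1e-8,
    ) -> None:
        self.graph = graph
        self.observed = observed
        self.scenario_id = scenario_id
        self.statistic_kind = observed.statistic_kind

        self._design = _FStatDesign(graph, observed.quartets)
        self._edge_order = self._design.edge_order
        self._admix_nodes = self._design.admix_nodes

        # observed f4 entries obey exact linear identities (they live in the
        # f-statistic subspace), so S may be rank-deficient by construction;
        # the pseudo-inverse restricts the cost to the informative subspace
        S = observed.S + ridge * np.eye(len(observed.entries))
        Sinv = np.linalg.pinv(S, hermitian=True, rcond=1e-10)
        lam, U = np.linalg.eigh(Sinv)
        lam = np.clip(lam, 0.0, None)
        self._whiten = (np.sqrt(lam) * U).T  # W with W^T W = Sinv
        self._b = self._whiten @ observed.values

        # identifiability: the two edges below the root contribute identical
        # coefficients to every f4, so their drifts are fused into one sum
        root_children_edges = [e for e in self._edge_order if e[0] == graph.root]
        self._fused = (
            tuple(root_children_edges) if len(root_children_edges) == 2 else None
        )
        fixed = set()
        if not fit_admixture_edge_drifts:
            for child, (p1, p2, _) in graph.admixture.items():
                fixed.update({(p1, child), (p2, child)})
        if self._fused:
            fixed.add(self._fused[1])  # carried by its partner's parameter
        self._free_edges = [e for e in self._edge_order if e not in fixed]
        self._free_ix = [self._edge_order.index(e) for e in self._free_edges]
        self._fixed_edges = fixed

    # ------------------------------------------------------------- cost

    @property
    def n_params(self) -> int:
        return len(self._free_edges) + len(self._admix_nodes)

    def _solve_drifts(self, alphas: np.ndarray):
        """Optimal nonnegative drift vector and cost for fixed alphas."""
        # fused root pair: the partner's (identical) column is excluded, so
        # the remaining root edge's estimate carries the pair's drift sum
        C = self._design.coefs(alphas)
        A = self._whiten @ C[:, self._free_ix]
        d, _ = nnls(A, self._b)
        r = A @ d - self._b
        return d, float(r @ r)

    def cost(self, x: np.ndarray) -> float:
        """Profiled Mahalanobis cost at logit-transformed alphas ``x``."""
        return self._solve_drifts(expit(np.asarray(x, dtype=float)))[1]

    def _initial_alphas(self, rng: np.random.Generator, jitter: float):
        a0 = np.array([self.graph.admixture[n][2] for n in self._admix_nodes])
        x = logit(np.clip(a0, 0.05, 0.95))
        return x + jitter * rng.standard_normal(len(x))

    # -------------------------------------------------------------- fit

    def fit(
        self,
        restarts: int = 50,
        seed: int | None = None,
        maxfev: int = 20_000,
        fatol: float = 1e-12,
        xatol: float = 1e-10,
        jitter: float = 1.5,
        polish_rounds: int = 3,
    ) -> ScenarioResults:
        """Minimise the cost by multi-restart Nelder--Mead over alphas.

        Each restart jitters the initial simplex in logit space; the best
        optimum is polished by re-running Nelder--Mead from it until the
        improvement stalls.  A scenario without admixture nodes is a single
        linear solve.
        """
        rng = np.random.default_rng(seed)
        opts = {"maxfev": maxfev, "fatol": fatol, "xatol": xatol}

        if not self._admix_nodes:
            d, err = self._solve_drifts(np.empty(0))
            best_x, best_f, converged = np.empty(0), err, True
        else:
            best_x, best_f, converged = None, np.inf, False
            for r in range(max(restarts, 1)):
                x0 = self._initial_alphas(rng, jitter if r else 0.0)
                res = minimize(self.cost, x0, method="Nelder-Mead", options=opts)
                if np.isfinite(res.fun) and res.fun < best_f:
                    best_x, best_f = res.x, float(res.fun)
                    converged = bool(res.success)
            if best_x is None:
                raise GraphError("cost was non-finite at every restart")
            for _ in range(polish_rounds):
                prev = best_f
                res = minimize(self.cost, best_x, method="Nelder-Mead",
                               options=opts)
                if res.fun < best_f:
                    best_x, best_f = res.x, float(res.fun)
                    converged = bool(res.success)
                if prev - best_f < 1e-15:
                    break
            d, _ = self._solve_drifts(expit(best_x))

        alphas = expit(best_x) if len(best_x) else np.empty(0)
        drifts = {e: 0.0 for e in self._fixed_edges}
        drifts.update(dict(zip(self._free_edges, d)))
        return ScenarioResults(
            scenario_id=self.scenario_id,
            graph=self.graph,
            drifts=drifts,
            alphas=dict(zip(self._admix_nodes, alphas)),
            scale=1.0,
            minimal_error=best_f,
            n_restarts=max(restarts, 1),
            converged=converged,
            statistic_kind=self.statistic_kind,
            fused_root_edges=self._fused,
        )


def fit_scenario(
    graph: AdmixtureGraph,
    observed: F4Vector,
    restarts: int = 50,
    seed: int | None = None,
    **kwargs,
) -> ScenarioResults:
    """Functional wrapper over :class:`ScenarioModel`."""
    return ScenarioModel(graph, observed, **kwargs).fit(restarts=restarts, seed=seed)


def compare_scenarios(
    scenarios: dict[str, AdmixtureGraph],
    observed: F4Vector,
    restarts: int = 50,
    seed: int | None = None,
    tie_tol: float = 1e-6,
    **kwargs,
) -> list[ScenarioResults]:
    """Fit every scenario to the same data and rank by minimal error.

    All scenarios must share the observed leaf set and receive the same
    restart budget.  Fits whose errors agree within ``tie_tol`` (relative)
    are ordered by parsimony: fewer admixture edges first.
    """
    if not scenarios:
        raise GraphError("no scenarios given")
    fits = []
    for i, (sid, g) in enumerate(scenarios.items()):
        model = ScenarioModel(g, observed, scenario_id=sid, **kwargs)
        fits.append(model.fit(restarts=restarts, seed=None if seed is None else seed + i))
    fits.sort(key=lambda f: f.minimal_error)
    # parsimony tie-break among near-equal errors
    changed = True
    while changed:
        changed = False
        for i in range(len(fits) - 1):
            a, b = fits[i], fits[i + 1]
            tol = tie_tol * (1.0 + abs(a.minimal_error))
            if (
                abs(a.minimal_error - b.minimal_error) < tol
                and b.graph.n_admixture < a.graph.n_admixture
            ):
                fits[i], fits[i + 1] = b, a
                changed = True
    return fits
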