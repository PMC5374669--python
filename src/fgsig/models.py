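"""Model builders: Poisson-binomial, PWM motifs, higher-order Markov motifs
and phylogenetic conservation under Jukes–Cantor.

Each builder compiles its application into a (FactorGraph, ScoreSpec) pair
so the generic tail machinery (normal/saddlepoint approximations, naive and
importance sampling, exact oracles) applies unchanged.  The alphabet order
is A, C, G, T throughout (JASPAR row order).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import logsumexp

import dendropy

from .graph import FactorGraph, build_factor_graph
from .scoring import ScoreSpec, log_odds_score
from .sampling import latent_statistic_tail

__all__ = [
    "ALPHABET",
    "MotifModel",
    "PhyloModel",
    "poisson_binomial_model",
    "pwm_model",
    "markov_model",
    "jc69_rate_matrix",
    "jc69_transition",
    "jc69_expected_substitutions",
    "expected_substitutions_matrix",
    "phylo_model",
    "max_score_pvalue",
]

ALPHABET = ("A", "C", "G", "T")


# ---------------------------------------------------------------------------
# Poisson-binomial

def poisson_binomial_model(p: Sequence[float], s: Sequence[float] | None = None
                           ) -> tuple[FactorGraph, ScoreSpec]:
    """N independent Bernoulli(p_n) events scored S = Σ s_n·Y_n (s defaults to 1).

    With equal p the score distribution is exactly Binomial(N, p).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty probability vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    weights = np.ones(p.size) if s is None else np.asarray(s, dtype=float)
    if weights.shape != p.shape:
        raise ValueError("weights must match probabilities in length")
    variables = [(f"y{n}", 2) for n in range(p.size)]
    factors = [(f"bern{n}", (f"y{n}",), np.array([1.0 - pn, pn])) for n, pn in enumerate(p)]
    graph = build_factor_graph(variables, factors)
    score = ScoreSpec(graph, [np.array([0.0, wn]) for wn in weights])
    return graph, score


# ---------------------------------------------------------------------------
# motif models

@dataclass
class MotifModel:
    """A compiled sequence-motif model.

    ``graph`` is the background (null) model and ``score`` the per-factor
    log-odds tables, so tails of S under ``graph`` are motif-match p-values.
    """

    length: int
    graph: FactorGraph
    score: ScoreSpec
    foreground: np.ndarray | dict
    background: np.ndarray | dict
    fg_graph: FactorGraph | None = None
    _window_scorer: Callable[[np.ndarray, int], np.ndarray] | None = field(
        default=None, repr=False)

    def window_scores(self, seqs: np.ndarray) -> np.ndarray:
        """Log-odds match score at every offset of integer-coded sequences (B, L)."""
        if self._window_scorer is None:
            raise NotImplementedError
        return self._window_scorer(np.asarray(seqs), self.length)


def pwm_model(pfm: np.ndarray, background: Sequence[float] | None = None,
              pseudocount: float = 0.01, kind: str = "auto") -> MotifModel:
    """Position weight matrix model over an i.i.d. background.

    ``pfm`` is 4×N (rows A,C,G,T), counts or column-normalized frequencies
    (``kind`` in {"auto", "counts", "frequencies"}).  Counts get
    ``pseudocount`` added per cell.  The compiled null graph has one 4-state
    variable per position with the background as (normalized) unary
    potential; scores are g_i(j) = log(f_ji / p_j).
    """
    pfm = np.asarray(pfm, dtype=float)
    if pfm.ndim != 2 or pfm.shape[0] != 4:
        raise ValueError("PFM must be a 4×N matrix (rows A,C,G,T)")
    if pfm.shape[1] < 1:
        raise ValueError("motif length must be >= 1")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or np.any(bg <= 0):
        raise ValueError("background must be a strictly positive 4-vector")
    bg = bg / bg.sum()
    col_sums = pfm.sum(axis=0)
    if np.any(col_sums <= 0):
        raise ValueError("PFM has a zero column total")
    if kind == "auto":
        kind = "frequencies" if np.allclose(col_sums, 1.0, atol=1e-6) else "counts"
    if kind == "counts":
        freqs = (pfm + pseudocount) / (col_sums + 4.0 * pseudocount)
    elif kind == "frequencies":
        freqs = pfm / col_sums
    else:
        raise ValueError("kind must be 'auto', 'counts' or 'frequencies'")
    if np.any(freqs == 0):
        raise ValueError("zero motif frequency with zero pseudocount: score unbounded")
    N = pfm.shape[1]
    variables = [(f"x{i}", 4) for i in range(N)]
    factors = [(f"pos{i}", (f"x{i}",), bg.copy()) for i in range(N)]
    graph = build_factor_graph(variables, factors)
    W = np.log(freqs / bg[:, None])          # 4×N log-odds matrix
    score = ScoreSpec(graph, [W[:, i] for i in range(N)])

    def scorer(seqs: np.ndarray, k: int) -> np.ndarray:
        B, L = seqs.shape
        out = np.zeros((B, L - k + 1))
        for off in range(L - k + 1):
            for i in range(k):
                out[:, off] += W[seqs[:, off + i], i]
        return out

    return MotifModel(length=N, graph=graph, score=score, foreground=freqs,
                      background=bg, _window_scorer=scorer)


def _compound_chain(A: int, r: int, L: int, initial: np.ndarray,
                    transitions: list[np.ndarray], prefix: str) -> FactorGraph:
    """First-order chain over A^r compound states for an order-r chain of length L."""
    K = A ** r
    n_comp = L - r + 1
    variables = [(f"{prefix}z{i}", K) for i in range(n_comp)]
    factors: list[tuple] = [(f"{prefix}init", (f"{prefix}z0",), initial)]
    # compound index encodes (x_i, ..., x_{i+r-1}) with the first symbol most significant
    suffix = np.arange(K) % (A ** (r - 1)) if r > 1 else np.zeros(K, dtype=int)
    for i in range(n_comp - 1):
        T = transitions[i]
        pot = np.zeros((K, K))
        for z in range(K):
            base = suffix[z] * A
            for nxt in range(A):
                pot[z, base + nxt] = T[z, nxt]
        factors.append((f"{prefix}step{i}", (f"{prefix}z{i}", f"{prefix}z{i + 1}"), pot))
    return build_factor_graph(variables, factors)


def markov_model(order: int, alphabet_size: int, initial: np.ndarray,
                 transitions, length: int, bg_initial: np.ndarray,
                 bg_transitions) -> MotifModel:
    """Order-r Markov motif versus an order-r Markov background, compounded
    to a first-order chain over A^r states so the graph is a tree.

    ``transitions`` / ``bg_transitions``: a single (A^r × A) row-stochastic
    table (homogeneous) or a list of L−r per-position tables.  Incompatible
    compound transitions carry zero potential and zero score.  The score is
    the log-odds of the foreground path probability to the background's.
    """
    r, A, L = int(order), int(alphabet_size), int(length)
    if not (L >= r >= 1):
        raise ValueError("need length >= order >= 1")
    K = A ** r
    n_steps = L - r

    def as_list(tr, what: str) -> list[np.ndarray]:
        arr = np.asarray(tr, dtype=float)
        if arr.ndim == 2:                      # homogeneous chain
            tr = [arr] * n_steps
        elif arr.ndim == 3:                    # one table per position
            tr = list(arr)
        else:
            raise ValueError(f"{what}: transitions must be a table or a list of tables")
        if len(tr) != n_steps:
            raise ValueError(f"{what}: expected {n_steps} per-position tables, got {len(tr)}")
        for t in tr:
            if t.shape != (K, A):
                raise ValueError(f"{what}: transition tables must be {K}×{A}")
            if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{what}: transition rows must sum to 1")
        return tr

    fg_init = np.asarray(initial, dtype=float)
    bg_init = np.asarray(bg_initial, dtype=float)
    for v, what in ((fg_init, "foreground"), (bg_init, "background")):
        if v.shape != (K,):
            raise ValueError(f"{what} initial distribution must have length {K}")
        if not np.isclose(v.sum(), 1.0, atol=1e-9):
            raise ValueError(f"{what} initial distribution must sum to 1")
    fg_tr = as_list(transitions, "foreground") if n_steps else []
    bg_tr = as_list(bg_transitions, "background") if n_steps else []

    fg_graph = _compound_chain(A, r, L, fg_init, fg_tr, prefix="")
    bg_graph = _compound_chain(A, r, L, bg_init, bg_tr, prefix="")
    score = log_odds_score(bg_graph, fg_graph)

    s_init = np.where(bg_init > 0, np.log(np.where(fg_init > 0, fg_init, 1.0) /
                                          np.where(bg_init > 0, bg_init, 1.0)), 0.0)
    s_steps = [np.where(b > 0, np.log(np.where(f > 0, f, 1.0) / np.where(b > 0, b, 1.0)), 0.0)
               for f, b in zip(fg_tr, bg_tr)]

    def scorer(seqs: np.ndarray, k: int) -> np.ndarray:
        B, Ls = seqs.shape
        out = np.zeros((B, Ls - k + 1))
        pow_ = A ** np.arange(r - 1, -1, -1)
        for off in range(Ls - k + 1):
            z = seqs[:, off:off + r] @ pow_
            acc = s_init[z]
            for i in range(n_steps):
                nxt = seqs[:, off + r + i]
                acc = acc + s_steps[i][z, nxt]
                z = (z % (A ** (r - 1))) * A + nxt if r > 1 else nxt
            out[:, off] = acc
        return out

    return MotifModel(length=L, graph=bg_graph, score=score,
                      foreground={"initial": fg_init, "transitions": fg_tr},
                      background={"initial": bg_init, "transitions": bg_tr},
                      fg_graph=fg_graph, _window_scorer=scorer)


# ---------------------------------------------------------------------------
# Jukes–Cantor substitution model

def jc69_rate_matrix(mu_total: float) -> np.ndarray:
    """JC69 generator with total leaving rate ``mu_total`` per unit time."""
    Q = np.full((4, 4), mu_total / 3.0)
    np.fill_diagonal(Q, -mu_total)
    return Q


def jc69_transition(mu_total: float, t: float) -> np.ndarray:
    """P(b | a, t): ¼ + ¾e^{−4μt/3} on the diagonal, ¼ − ¼e^{−4μt/3} off it."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if mu_total <= 0:
        raise ValueError("substitution rate must be positive")
    e = math.exp(-4.0 / 3.0 * mu_total * t)
    P = np.full((4, 4), 0.25 - 0.25 * e)
    np.fill_diagonal(P, 0.25 + 0.75 * e)
    return P


def expected_substitutions_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """E[# substitution events in (0,t) | X_0=a, X_t=b] for generator Q.

    Events are counted by C = Q with the diagonal zeroed, via
    M(t) = ∫₀ᵗ e^{Qs} C e^{Q(t−s)} ds evaluated in the eigenbasis of Q, then
    E = M / P elementwise with P = e^{Qt}.  Multiple substitutions at the
    same site can cancel, so E[N|a,a] > 0 for every t > 0.
    """
    if t <= 0:
        raise ValueError("branch length must be positive")
    Q = np.asarray(Q, dtype=float)
    C = Q - np.diag(np.diag(Q))
    lam, V = np.linalg.eig(Q)
    Vinv = np.linalg.inv(V)
    A = Vinv @ C @ V
    el = np.exp(lam * t)
    diff = lam[:, None] - lam[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        I = (el[:, None] - el[None, :]) / diff
    same = np.isclose(diff, 0.0, atol=1e-12)
    I[same] = (t * el[:, None] * np.ones_like(I))[same]
    M = (V @ (A * I) @ Vinv).real
    P = (V @ np.diag(el) @ Vinv).real
    return M / P


def jc69_expected_substitutions(mu_total: float, t: float) -> np.ndarray:
    """Conditional expected substitution counts on a JC69 branch of length μt."""
    return expected_substitutions_matrix(jc69_rate_matrix(mu_total), t)


# ---------------------------------------------------------------------------
# phylogenetic conservation model

@dataclass
class PhyloModel:
    """A Newick tree compiled to a factor graph with substitution-count scores.

    One 4-state variable per node (root first, preorder); a uniform root
    prior factor; one pairwise factor per branch carrying the JC69
    transition matrix, scored with the branch's conditional expected
    substitution counts.  The statistic of record for an alignment column
    is the posterior expected number of substitutions over the whole tree
    given the leaf states.
    """

    tree: dendropy.Tree
    mu_total: float
    graph: FactorGraph
    score: ScoreSpec
    leaf_names: list[str]
    _branches: list[tuple[int, np.ndarray, np.ndarray]] = field(repr=False, default=None)  # type: ignore[assignment]

    def column_evidence(self, column: Sequence[int] | dict[str, int]) -> dict[str, int]:
        """Evidence dict from leaf states (sequence in ``leaf_names`` order, or a map)."""
        if isinstance(column, dict):
            return {name: int(column[name]) for name in self.leaf_names}
        if len(column) != len(self.leaf_names):
            raise ValueError("column length must equal the number of leaves")
        return {name: int(s) for name, s in zip(self.leaf_names, column)}

    def expected_substitutions(self, columns: np.ndarray) -> np.ndarray:
        """Posterior E[# substitutions | leaf column], vectorized over columns.

        ``columns``: (B, n_leaves) integer states in ``leaf_names`` order.
        A batched pruning pass propagating (log-mass, conditional-mean)
        pairs from the leaves to the root; cross-checked in the test suite
        against the generic per-column posterior_expected_score.
        """
        columns = np.atleast_2d(np.asarray(columns, dtype=np.int64))
        B = columns.shape[0]
        lm: dict[int, np.ndarray] = {}
        mu: dict[int, np.ndarray] = {}
        leaf_pos = {name: i for i, name in enumerate(self.leaf_names)}
        for node in self.tree.postorder_node_iter():
            nid = id(node)
            if node.is_leaf():
                states = columns[:, leaf_pos[node.taxon.label]]
                l = np.full((B, 4), -np.inf)
                l[np.arange(B), states] = 0.0
                lm[nid], mu[nid] = l, np.zeros((B, 4))
            else:
                l = np.zeros((B, 4))
                m = np.zeros((B, 4))
                for child in node.child_nodes():
                    cid = id(child)
                    T, E = self._branch_tables[cid]
                    a = lm[cid].max(axis=1, keepdims=True)
                    a = np.where(np.isfinite(a), a, 0.0)
                    W = np.exp(lm[cid] - a)                      # (B,4) child-state masses
                    mass = W @ T.T                               # (B,4) over parent state
                    num = (W * mu[cid]) @ T.T + W @ (T * E).T
                    with np.errstate(divide="ignore", invalid="ignore"):
                        l = l + np.where(mass > 0, np.log(mass), -np.inf) + a
                        m = m + np.where(mass > 0, num / np.where(mass > 0, mass, 1.0), 0.0)
                    del lm[cid], mu[cid]
                lm[nid], mu[nid] = l, m
        root = id(self.tree.seed_node)
        l, m = lm[root], mu[root]
        a = l.max(axis=1, keepdims=True)
        W = np.exp(l - a) * 0.25
        Z = W.sum(axis=1)
        return (W * m).sum(axis=1) / Z

    def statistic_tail(self, t: float, alpha: float = 0.0, n: int = 10_000, seed: int = 0,
                       tail_side: str = "lower"):
        """Significance of the conservation statistic via latent-variable IS.

        Lower tail (few substitutions) tests conservation; the upper tail
        tests acceleration.  ``alpha`` tilts the full-data distribution
        (negative values favour conserved columns).
        """
        return latent_statistic_tail(self.graph, self.score, self.leaf_names,
                                     self.expected_substitutions, t,
                                     alpha=alpha, n=n, seed=seed, tail_side=tail_side)

    @property
    def _branch_tables(self) -> dict[int, tuple[np.ndarray, np.ndarray]]:
        cache = self.graph._cache.get("phylo_branches")
        if cache is None:
            cache = {}
            for child, T, E in self._branches:
                cache[child] = (T, E)
            self.graph._cache["phylo_branches"] = cache
        return cache


def phylo_model(newick: str, mu_total: float = 1.0) -> PhyloModel:
    """Compile a rooted Newick tree (branch lengths in expected substitutions
    per site when ``mu_total`` is 1) into a JC69 conservation model."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    leaves = [lf for lf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")

    names: dict[int, str] = {}
    internal = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            if node.taxon is None or not node.taxon.label:
                raise ValueError("every leaf must be labelled")
            names[id(node)] = node.taxon.label
        else:
            names[id(node)] = f"_node{internal}"
            internal += 1

    variables = [(names[id(node)], 4) for node in tree.preorder_node_iter()]
    root_name = names[id(tree.seed_node)]
    factors: list[tuple] = [("root_prior", (root_name,), np.full(4, 0.25))]
    tables: list[np.ndarray] = [np.zeros(4)]
    branches = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            raise ValueError(f"branch above {names[id(node)]!r} has no length")
        T = jc69_transition(mu_total, float(node.edge.length))
        E = jc69_expected_substitutions(mu_total, float(node.edge.length))
        factors.append((f"branch_{names[id(node)]}",
                        (names[id(node.parent_node)], names[id(node)]), T))
        tables.append(E)
        branches.append((id(node), T, E))
    graph = build_factor_graph(variables, factors)
    score = ScoreSpec(graph, tables)
    model = PhyloModel(tree=tree, mu_total=mu_total, graph=graph, score=score,
                       leaf_names=[names[id(lf)] for lf in leaves])
    model._branches = branches
    return model


# ---------------------------------------------------------------------------
# scan maxima

def max_score_pvalue(single_match_p: float, sequence_length: int, motif_length: int) -> float:
    """Poisson approximation for the max match score over all offsets.

    A motif of length k can start at M = L − k + 1 offsets;
    P(max > t) ≈ 1 − exp(−M·p) with p the single-match p-value.  The
    approximation degrades when M·p is not small or the motif is
    low-complexity (overlapping matches clump).
    """
    if not 0.0 <= single_match_p <= 1.0:
        raise ValueError("single-match p-value must lie in [0, 1]")
    if sequence_length < motif_length:
        raise ValueError("sequence shorter than the motif")
    M = sequence_length - motif_length + 1
    if M * single_match_p > 0.5:
        warnings.warn(f"Poisson approximation unreliable: M*p = {M * single_match_p:.3g} > 0.5",
                      stacklevel=2)
    return float(-math.expm1(-M * single_match_p))
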