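"""Independent exact oracles and seeded synthetic fixtures.

Everything here validates the message-passing machinery without sharing a
code path with it: tails and cumulants by exhaustive enumeration over the
full joint state space, sums of independent contributions by iterated
convolution of score distributions, and JC69 conditional substitution
counts by continuous-time Markov chain path simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .graph import FactorGraph, build_factor_graph
from .scoring import ScoreSpec

__all__ = [
    "FIXTURE_TREE_11",
    "ScoreDistribution",
    "enumerate_joint",
    "enumerate_tail",
    "enumerate_distribution",
    "enumerate_cgf",
    "convolve_all",
    "convolution_tail",
    "balanced_tree_fixture",
    "random_tree_fixture",
    "simulate_ctmc",
    "CtmcSummary",
]

MAX_CONFIGURATIONS = 2_000_000

#: Synthetic 11-leaf phylogeny (branch lengths in expected substitutions per
#: site, total tree length 13.2 — a deep, phyloP-style alignment where the
#: column statistic averages ~13 substitutions) used as the standing
#: conservation fixture.
FIXTURE_TREE_11 = (
    "((((L1:0.64,L2:0.96):0.4,(L3:0.8,L4:0.56):0.72):0.48,"
    "((L5:0.88,L6:0.48):0.64,(L7:0.72,L8:1.04):0.56):0.4):0.32,"
    "(L9:0.8,(L10:0.96,L11:0.64):0.48):0.72);"
)


@dataclass
class ScoreDistribution:
    """A finite score distribution: strictly increasing support + probabilities."""

    support: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.support.shape != self.probs.shape:
            raise ValueError("support and probabilities must have equal length")
        if np.any(np.diff(self.support) <= 0):
            raise ValueError("support must be strictly increasing")
        if abs(self.probs.sum() - 1.0) > 1e-12 * max(1.0, self.probs.size):
            raise ValueError("probabilities must sum to 1")

    def tail(self, t: float) -> float:
        return float(self.probs[self.support > t].sum())


# ---------------------------------------------------------------------------
# enumeration

def enumerate_joint(graph: FactorGraph, score: ScoreSpec) -> tuple[np.ndarray, np.ndarray]:
    """(log-weights, scores) flattened over the full joint state space.

    Built by direct broadcasting of the factor tables over the joint tensor;
    no messages involved.
    """
    if graph.n_configurations > MAX_CONFIGURATIONS:
        raise ValueError(f"state space too large to enumerate ({graph.n_configurations} configurations)")
    nv = len(graph.variables)
    cards = [v.n_states for v in graph.variables]
    logw = np.zeros(cards)
    total = np.zeros(cards)
    for f, g in zip(graph.factors, score.tables):
        axes = [graph.var_index[n] for n in f.scope]
        order = np.argsort(axes)
        lp = np.transpose(f.log_potential, order)
        gt = np.transpose(np.where(f.log_potential == -np.inf, 0.0, g), order)
        shape = [1] * nv
        for a in sorted(axes):
            shape[a] = cards[a]
        logw = logw + lp.reshape(shape)
        total = total + gt.reshape(shape)
    return logw.ravel(), total.ravel()


def enumerate_tail(graph: FactorGraph, score: ScoreSpec, t: float) -> float:
    """Exact P(S > t) by exhaustive enumeration."""
    logw, s = enumerate_joint(graph, score)
    with np.errstate(divide="ignore"):
        log_Z = logsumexp(logw)
    if log_Z == -np.inf:
        raise ArithmeticError("graph has zero total mass")
    mask = s > t
    if not mask.any():
        return 0.0
    return float(np.exp(logsumexp(logw[mask]) - log_Z))


def enumerate_distribution(graph: FactorGraph, score: ScoreSpec,
                           merge_tol: float = 1e-12) -> ScoreDistribution:
    """Exact distribution of S, with near-equal support points merged."""
    logw, s = enumerate_joint(graph, score)
    with np.errstate(divide="ignore"):
        p = np.exp(logw - logsumexp(logw))
    return _merge(s, p, merge_tol)


def enumerate_cgf(graph: FactorGraph, score: ScoreSpec, theta: float
                  ) -> tuple[float, float, float]:
    """Exact (κ, κ′, κ″) at θ by direct summation over configurations."""
    logw, s = enumerate_joint(graph, score)
    with np.errstate(divide="ignore"):
        log_Z = logsumexp(logw)
        tilted = logw + theta * s
        log_Zt = logsumexp(tilted)
    w = np.exp(tilted - log_Zt)
    m1 = float(np.sum(w * s))
    m2 = float(np.sum(w * s * s))
    return float(log_Zt - log_Z), m1, m2 - m1 * m1


# ---------------------------------------------------------------------------
# convolution

def _merge(support: np.ndarray, probs: np.ndarray, tol: float) -> ScoreDistribution:
    order = np.argsort(support, kind="stable")
    s, p = support[order], probs[order]
    keep = s[1:] - s[:-1] > tol
    group = np.concatenate([[0], np.cumsum(keep)])
    out_s = np.zeros(group[-1] + 1)
    out_p = np.zeros(group[-1] + 1)
    np.add.at(out_p, group, p)
    # representative point: first of each group
    first = np.concatenate([[True], keep])
    out_s = s[first]
    return ScoreDistribution(out_s, out_p / out_p.sum())


def convolve_all(components: list[ScoreDistribution], merge_tol: float = 1e-12
                 ) -> ScoreDistribution:
    """Exact distribution of the sum of independent components."""
    if not components:
        raise ValueError("need at least one component")
    acc = components[0]
    for comp in components[1:]:
        s = (acc.support[:, None] + comp.support[None, :]).ravel()
        p = (acc.probs[:, None] * comp.probs[None, :]).ravel()
        acc = _merge(s, p, merge_tol)
    return acc


def convolution_tail(components: list[ScoreDistribution], t: float) -> float:
    """Exact P(Σ S_i > t) for independent components."""
    return convolve_all(components).tail(t)


# ---------------------------------------------------------------------------
# fixtures

def balanced_tree_fixture(depth: int, degree: int, states: int = 3,
                          score_dialect: str = "continuous", seed: int = 0,
                          coupling: float = 0.5) -> tuple[FactorGraph, ScoreSpec]:
    """Balanced variable tree with a tunable dependence knob.

    Each edge carries the stationary channel P(child=k | parent=j) =
    (1−c)·π_k + c·1[k=j] with a seeded skewed base distribution π (root
    prior π as well), so every node marginal is π and every factor's score
    contribution h(X_node) — one score vector h shared across factors — has
    the same marginal distribution.  ``coupling`` c interpolates between
    fully independent node states (c=0, variance ratio 1) and strongly
    coupled ones, moving the variance ratio monotonically.  Score dialects
    (each factor scores only its child — root: its own — state):
    ``continuous`` draws a fresh standard-normal score vector per factor
    (contributions share the N(0,1)-mixture family and the support stays
    rich); ``lattice`` draws small integers per factor; ``loglik`` scores
    every node with the shared surprisal vector h = −log π, making the
    contributions exactly identically distributed (used for the
    variance-ratio dependence sweep).
    """
    if not 0.0 <= coupling < 1.0:
        raise ValueError("coupling must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    K = states
    pi = rng.dirichlet(np.full(K, 1.5))
    pi = np.maximum(pi, 0.02)
    pi = pi / pi.sum()
    channel = (1.0 - coupling) * np.tile(pi, (K, 1)) + coupling * np.eye(K)

    def draw() -> np.ndarray:
        if score_dialect == "continuous":
            return rng.standard_normal(K)
        if score_dialect == "lattice":
            return rng.integers(0, 3, K).astype(float)
        if score_dialect == "loglik":
            return -np.log(pi)
        raise ValueError("score_dialect must be 'continuous', 'lattice' or 'loglik'")

    variables = [("v0", K)]
    factors = [("prior", ("v0",), pi.copy())]
    tables = [draw()]
    frontier = ["v0"]
    idx = 1
    for _ in range(depth):
        new_frontier = []
        for parent in frontier:
            for _ in range(degree):
                child = f"v{idx}"
                idx += 1
                variables.append((child, K))
                factors.append((f"edge_{child}", (parent, child), channel.copy()))
                tables.append(np.tile(draw(), (K, 1)))
                new_frontier.append(child)
        frontier = new_frontier
    graph = build_factor_graph(variables, factors)
    return graph, ScoreSpec(graph, tables)


def markov_motif_fixture(seed: int = 0, length: int = 16, order: int = 2):
    """A BaMM-style order-2 motif of 16 bp over a homogeneous order-2 background.

    Foreground: per-position transition rows drawn Dirichlet(0.5) — an
    informative, context-dependent motif; initial distribution Dirichlet(0.5)
    over the 16 starting dinucleotides.  Background: one homogeneous
    transition table with rows Dirichlet(10) (mildly non-uniform, genomic
    composition-like), started from its stationary context distribution so
    that every scan offset sees the same match-score law.
    """
    from .models import markov_model

    rng = np.random.default_rng(seed)
    A, K = 4, 4 ** order
    fg_init = rng.dirichlet(np.full(K, 0.5))
    fg_tr = [rng.dirichlet(np.full(A, 0.5), size=K) for _ in range(length - order)]
    bg_tr = rng.dirichlet(np.full(A, 10.0), size=K)
    # stationary distribution of the compound (context -> context) chain
    T = np.zeros((K, K))
    for z in range(K):
        for nxt in range(A):
            T[z, (z % (A ** (order - 1))) * A + nxt] = bg_tr[z, nxt]
    vals, vecs = np.linalg.eig(T.T)
    stat = np.real(vecs[:, np.argmax(np.real(vals))])
    bg_init = np.abs(stat) / np.abs(stat).sum()
    return markov_model(order, A, fg_init, fg_tr, length, bg_init,
                        [bg_tr] * (length - order))


def random_tree_fixture(n_vars: int, max_states: int = 4, seed: int = 0
                        ) -> tuple[FactorGraph, ScoreSpec]:
    """A random tree graph with gamma-distributed potentials and normal scores.

    Variable i (i ≥ 1) attaches to a uniformly chosen earlier variable with
    a pairwise factor; the root gets a unary prior.  Used for the
    oracle-equivalence checks.
    """
    rng = np.random.default_rng(seed)
    cards = rng.integers(2, max_states + 1, n_vars)
    variables = [(f"x{i}", int(cards[i])) for i in range(n_vars)]
    factors = [("prior", ("x0",), rng.gamma(1.0, 1.0, int(cards[0])) + 1e-3)]
    tables = [rng.standard_normal(int(cards[0]))]
    for i in range(1, n_vars):
        j = int(rng.integers(0, i))
        pot = rng.gamma(1.0, 1.0, (int(cards[j]), int(cards[i]))) + 1e-3
        factors.append((f"edge{i}", (f"x{j}", f"x{i}"), pot))
        tables.append(rng.standard_normal((int(cards[j]), int(cards[i]))))
    graph = build_factor_graph(variables, factors)
    return graph, ScoreSpec(graph, tables)


# ---------------------------------------------------------------------------
# CTMC path simulation

@dataclass
class CtmcSummary:
    endpoint_probs: np.ndarray       # empirical P(b | a, t), length 4
    endpoint_probs_se: np.ndarray
    mean_subs: np.ndarray            # empirical E[N | a, b, t], length 4 (NaN if unvisited)
    mean_subs_se: np.ndarray
    n_paths: int


def simulate_ctmc(mu_total: float, t: float, start: int, n: int, seed: int = 0) -> CtmcSummary:
    """Gillespie-style JC69 path simulation.

    Under JC69 the total leaving rate is state-independent, so event times
    are a Poisson(μt) process and each event jumps uniformly to one of the
    three other states; every event is a substitution.
    """
    if n < 1:
        raise ValueError("need at least one path")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(mu_total * t, n)
    state = np.full(n, start, dtype=np.int64)
    for j in range(int(counts.max()) if n else 0):
        active = counts > j
        state[active] = (state[active] + rng.integers(1, 4, int(active.sum()))) % 4
    probs = np.zeros(4)
    probs_se = np.zeros(4)
    means = np.full(4, np.nan)
    means_se = np.full(4, np.nan)
    for b in range(4):
        mask = state == b
        nb = int(mask.sum())
        phat = nb / n
        probs[b] = phat
        probs_se[b] = np.sqrt(phat * (1.0 - phat) / n)
        if nb > 1:
            means[b] = counts[mask].mean()
            means_se[b] = counts[mask].std(ddof=1) / np.sqrt(nb)
    return CtmcSummary(probs, probs_se, means, means_se, n)
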