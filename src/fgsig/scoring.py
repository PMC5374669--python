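"""Additive scores, exponential tilting and exact cumulants.

A score S(x) = Σ_a g_a(x_a) assigns one table per factor, shaped like the
factor's potential.  Exponentially tilting the graph by α multiplies each
potential by exp(α·g_a), which is again a factor graph with the same
structure, so the whole exponential family {P_θ} is reachable by message
passing on tilted graphs.

The cumulant generating function κ(θ) = log E[e^{θS}] and its first two
derivatives are computed *exactly* in a single leaf-to-root pass of moment
triples (mass, first score moment, second score moment) — an expectation
semiring over the tilted graph.  In the numerically safe representation a
triple is (log-mass, mean part, second-moment part):

    product  (independent parts):  (z1+z2, μ1+μ2, q1 + 2 μ1 μ2 + q2)
    state summation:               mass-weighted averaging of μ and q

κ′(θ) is the tilted mean E_θ[S] and κ″(θ) the tilted variance V_θ[S].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .graph import FactorGraph
from .inference import ZeroMassError, _broadcast, _tree, sum_product

__all__ = [
    "ScoreSpec",
    "MomentTriple",
    "CgfResult",
    "log_likelihood_score",
    "log_odds_score",
    "tilt",
    "cgf_moments",
    "score_mean_variance",
    "variance_ratio",
]


class ScoreSpec:
    """Per-factor score tables realizing S(x) = Σ_a g_a(x_a).

    Infinite entries are admitted only on zero-mass states of the factor
    they belong to, so that S is finite for every positive-mass
    configuration.
    """

    def __init__(self, graph: FactorGraph, tables: Sequence[np.ndarray]):
        if len(tables) != len(graph.factors):
            raise ValueError(f"expected {len(graph.factors)} score tables, got {len(tables)}")
        checked = []
        for f, t in zip(graph.factors, tables):
            t = np.asarray(t, dtype=float)
            if t.shape != f.potential.shape:
                raise ValueError(f"score table for factor {f.name!r} has shape {t.shape}, "
                                 f"expected {f.potential.shape}")
            if np.any(np.isnan(t)):
                raise ValueError(f"score table for factor {f.name!r} contains NaN")
            bad = ~np.isfinite(t) & (f.log_potential > -np.inf)
            if np.any(bad):
                raise ValueError(f"score table for factor {f.name!r} is infinite on a "
                                 f"positive-mass state")
            checked.append(t)
        self.tables = tuple(checked)

    def negated(self, graph: FactorGraph) -> "ScoreSpec":
        return ScoreSpec(graph, [-t for t in self.tables])


@dataclass(frozen=True)
class MomentTriple:
    """Scaled expectation-semiring payload: (log mass, E-part, E²-part)."""

    log_mass: float
    mean_part: float
    second_part: float

    def __mul__(self, other: "MomentTriple") -> "MomentTriple":
        return MomentTriple(
            self.log_mass + other.log_mass,
            self.mean_part + other.mean_part,
            self.second_part + 2.0 * self.mean_part * other.mean_part + other.second_part,
        )


@dataclass(frozen=True)
class CgfResult:
    theta: float
    kappa: float
    kappa1: float
    kappa2: float


def _masked_scores(graph: FactorGraph, score: ScoreSpec) -> list[np.ndarray]:
    """Score tables with zero-mass states forced to 0 (their value is irrelevant)."""
    return [np.where(f.log_potential == -np.inf, 0.0, t)
            for f, t in zip(graph.factors, score.tables)]


def log_likelihood_score(graph: FactorGraph) -> ScoreSpec:
    """g_a = −log f_a, so S(x) = −log Π f_a(x_a) (= −log P(x) when normalized)."""
    from .graph import is_normalized

    if not is_normalized(graph, 1e-6):
        warnings.warn("log-likelihood score on an unnormalized graph: S(x) = "
                      "−log Π f_a differs from −log P(x) by log Z", stacklevel=2)
    return ScoreSpec(graph, [-f.log_potential for f in graph.factors])


def log_odds_score(bg: FactorGraph, fg: FactorGraph) -> ScoreSpec:
    """g_a = log(f_a^fg / f_a^bg), comparing a foreground to a background model."""
    if len(bg.factors) != len(fg.factors) or len(bg.variables) != len(fg.variables):
        raise ValueError("foreground and background graphs differ in structure")
    tables = []
    for fb, ff in zip(bg.factors, fg.factors):
        if fb.scope != ff.scope or fb.potential.shape != ff.potential.shape:
            raise ValueError(f"factor {fb.name!r}: scope/shape mismatch between models")
        if np.any((fb.log_potential == -np.inf) & (ff.log_potential > -np.inf)):
            raise ValueError(f"factor {fb.name!r}: foreground positive where background "
                             f"is zero (unbounded odds)")
        zero_both = fb.log_potential == -np.inf
        fg_zero = (ff.log_potential == -np.inf) & ~zero_both
        if np.any(fg_zero):
            raise ValueError(f"factor {fb.name!r}: foreground zero on a positive-mass "
                             f"background state (score unbounded below)")
        with np.errstate(invalid="ignore"):
            g = np.where(zero_both, 0.0, ff.log_potential - fb.log_potential)
        tables.append(g)
    return ScoreSpec(bg, tables)


def tilt(graph: FactorGraph, score: ScoreSpec, alpha: float) -> FactorGraph:
    """Tilted graph with f̃_{a,α} = f_a · exp(α g_a); same structure, generally unnormalized."""
    masked = _masked_scores(graph, score)
    log_pots = [np.where(f.log_potential == -np.inf, -np.inf, f.log_potential + alpha * g)
                for f, g in zip(graph.factors, masked)]
    return graph.copy_with_log_potentials(log_pots)


# ---------------------------------------------------------------------------
# moment-semiring message passing

def _combine_parts(lms, mus, qs):
    """Product of independent array triples broadcast to a common shape."""
    lm = sum(lms)
    mu = sum(mus)
    q = sum(qs) + mu * mu - sum(m * m for m in mus)
    return lm, mu, q


def _marginalize_triple(lm, mu, q, keep_axis):
    axes = tuple(a for a in range(lm.ndim) if a != keep_axis)
    if not axes:
        return lm, mu, q
    with np.errstate(divide="ignore"):
        LM = logsumexp(lm, axis=axes, keepdims=True)
    w = np.where(lm == -np.inf, 0.0, np.exp(lm - np.where(LM == -np.inf, 0.0, LM)))
    MU = np.sum(w * mu, axis=axes)
    Q = np.sum(w * q, axis=axes)
    return np.squeeze(LM, axis=axes), MU, Q


def _moment_pass(graph: FactorGraph, score: ScoreSpec, theta: float):
    """One leaf-to-root pass: returns (log Z̃(θ), E_θ[S], E_θ[S²])."""
    tree = _tree(graph)
    masked = _masked_scores(graph, score)
    msgs: dict[tuple[int, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    up_vf: dict[tuple[str, int], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    for node in reversed(tree.order):
        kind, idx = node
        par = tree.parent[node]
        if kind == "f":
            f = graph.factors[idx]
            g = masked[idx]
            lm = np.where(f.log_potential == -np.inf, -np.inf, f.log_potential + theta * g)
            lms, mus, qs = [lm], [g], [g * g]
            pname = graph.variables[par[1]].name
            keep_axis = None
            for axis, name in enumerate(f.scope):
                if name == pname:
                    keep_axis = axis
                    continue
                clm, cmu, cq = up_vf[(name, idx)]
                lms.append(_broadcast(clm, axis, lm.ndim))
                mus.append(_broadcast(cmu, axis, lm.ndim))
                qs.append(_broadcast(cq, axis, lm.ndim))
            lm, mu, q = _combine_parts(lms, mus, qs)
            msgs[(idx, pname)] = _marginalize_triple(lm, mu, q, keep_axis)
        else:
            name = graph.variables[idx].name
            n = graph.variables[idx].n_states
            pj = par[1] if par is not None else None
            lms, mus, qs = [np.zeros(n)], [np.zeros(n)], [np.zeros(n)]
            for j in graph.var_factors[name]:
                if j != pj:
                    clm, cmu, cq = msgs[(j, name)]
                    lms.append(clm)
                    mus.append(cmu)
                    qs.append(cq)
            up_vf[(name, pj)] = _combine_parts(lms, mus, qs) if pj is not None else None
            if par is None:
                lm, mu, q = _combine_parts(lms, mus, qs)
                graph._cache.setdefault("_root_triples", {})[idx] = \
                    _marginalize_triple(lm, mu, q, keep_axis=None)

    # combine the per-component root triples with the product rule
    log_mass, mean, second = 0.0, 0.0, 0.0
    root_triples = graph._cache.pop("_root_triples")
    for r in tree.roots:
        lm_r, mu_r, q_r = (float(x) for x in root_triples[r])
        if lm_r == -np.inf:
            raise ZeroMassError("tilted graph has zero partition function")
        second = second + q_r + 2.0 * mean * mu_r
        mean = mean + mu_r
        log_mass = log_mass + lm_r
    return log_mass, mean, second


def cgf_moments(graph: FactorGraph, score: ScoreSpec, theta: float) -> CgfResult:
    """Exact κ(θ), κ′(θ), κ″(θ) of the score under the graph's distribution."""
    log_mass, mean, second = _moment_pass(graph, score, float(theta))
    log_Z0 = sum_product(graph).log_Z if theta != 0.0 else log_mass
    kappa = log_mass - log_Z0
    kappa2 = second - mean * mean
    if kappa2 < 0.0:
        # strictly non-negative in exact arithmetic; tolerate rounding only
        if kappa2 < -1e-9 * max(1.0, abs(second)):
            raise ArithmeticError(f"negative tilted variance {kappa2}")
        kappa2 = 0.0
    return CgfResult(float(theta), float(kappa), float(mean), float(kappa2))


def score_mean_variance(graph: FactorGraph, score: ScoreSpec) -> tuple[float, float]:
    """(E[S], V[S]) = (κ′(0), κ″(0))."""
    r = cgf_moments(graph, score, 0.0)
    return r.kappa1, r.kappa2


def variance_ratio(graph: FactorGraph, score: ScoreSpec) -> float:
    """V[S] over Σ_a V[g_a(X_a)] — 1 under independence, else a dependence diagnostic."""
    res = sum_product(graph)
    masked = _masked_scores(graph, score)
    denom = 0.0
    for f, g in zip(graph.factors, masked):
        marg = res.factor_marginals[f.name]
        m1 = float(np.sum(marg * g))
        m2 = float(np.sum(marg * g * g))
        denom += m2 - m1 * m1
    if denom <= 1e-12:
        raise ValueError("degenerate score: every factor contribution is constant")
    return cgf_moments(graph, score, 0.0).kappa2 / denom
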