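"""Forward sampling and (importance-)sampling tail estimators.

Sampling descends the same rooted traversal used by inference: the root
variable of each component is drawn from its marginal, then each factor
draws its not-yet-assigned scope variables from the factor potential times
the upward messages of their subtrees, conditioned on the already assigned
neighbour.  All n draws are carried through the descent as one vectorized
batch from a single seeded generator, so results are reproducible given
(graph, n, seed).

Importance sampling draws from the exponentially tilted graph; the weight
of a sample is w = P(x)/P̃_α(x) = exp(κ(α) − α·S(x)) exactly (the
unnormalized case enters through κ(α) = log Z̃(α) − log Z̃(0)), and

    P(S > t) ≈ (1/N) Σ w_i · 1(s_i > t).

α = 0 recovers naive sampling (all weights 1).  The saddlepoint-guided
choice α = θ(t) makes the proposal's mean score equal the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .graph import FactorGraph
from .inference import _messages, _tree, _var_belief, posterior_expected_score
from .scoring import ScoreSpec, _masked_scores, cgf_moments, tilt
from .tails import TailEstimate, solve_saddlepoint

__all__ = [
    "SampleBatch",
    "forward_sample",
    "sample_scores",
    "importance_sample_tail",
    "saddlepoint_guided_alpha",
    "latent_statistic_tail",
]


@dataclass
class SampleBatch:
    scores: np.ndarray
    log_weights: np.ndarray
    alpha: float
    seed: int
    n: int


def _categorical_rows(rng: np.random.Generator, prob_rows: np.ndarray) -> np.ndarray:
    """One draw per row from the categorical distribution given by each row."""
    cdf = np.cumsum(prob_rows, axis=1)
    u = rng.random(prob_rows.shape[0]) * cdf[:, -1]
    return np.minimum((u[:, None] > cdf).sum(axis=1), prob_rows.shape[1] - 1)


def forward_sample(graph: FactorGraph, n: int, seed: int) -> np.ndarray:
    """n exact draws from the graph's normalized distribution, shape (n, n_vars)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    from .inference import sum_product

    sum_product(graph)  # raises on zero mass; fills the message cache
    tree = _tree(graph)
    m_fv, m_vf = _messages(graph)
    rng = np.random.default_rng(seed)
    nv = len(graph.variables)
    configs = np.empty((n, nv), dtype=np.int64)

    for node in tree.order:
        kind, idx = node
        if kind == "v":
            if tree.parent[node] is not None:
                continue  # assigned when its parent factor was processed
            b = _var_belief(graph, idx, m_fv)
            with np.errstate(divide="ignore"):
                probs = np.exp(b - logsumexp(b))
            configs[:, idx] = _categorical_rows(rng, np.broadcast_to(probs, (n, probs.size)))
        else:
            f = graph.factors[idx]
            pname = graph.variables[tree.parent[node][1]].name
            children = [c for c in f.scope if c != pname]
            if not children:
                continue
            t = f.log_potential
            p_axis = None
            for axis, name in enumerate(f.scope):
                if name == pname:
                    p_axis = axis
                else:
                    msg = m_vf[(name, idx)]
                    shape = [1] * t.ndim
                    shape[axis] = msg.shape[0]
                    t = t + msg.reshape(shape)
            t = np.moveaxis(t, p_axis, 0)
            child_dims = t.shape[1:]
            flat = t.reshape(t.shape[0], -1)
            with np.errstate(divide="ignore"):
                lz = logsumexp(flat, axis=1, keepdims=True)
            rows = np.where(flat == -np.inf, 0.0, np.exp(flat - np.where(lz == -np.inf, 0.0, lz)))
            pa = configs[:, graph.var_index[pname]]
            drawn = _categorical_rows(rng, rows[pa])
            states = np.unravel_index(drawn, child_dims)
            for cname, st in zip(children, states):
                configs[:, graph.var_index[cname]] = st
    return configs


def sample_scores(graph: FactorGraph, score: ScoreSpec, configs: np.ndarray) -> np.ndarray:
    """S(x) for each row of ``configs`` (columns in variable declaration order)."""
    masked = _masked_scores(graph, score)
    total = np.zeros(configs.shape[0])
    for f, g in zip(graph.factors, masked):
        cols = tuple(configs[:, graph.var_index[name]] for name in f.scope)
        total += g[cols]
    return total


def saddlepoint_guided_alpha(graph: FactorGraph, score: ScoreSpec, t: float) -> float:
    """SG-IS tilting parameter: the saddlepoint θ(t), so that E_α[S] = t."""
    return solve_saddlepoint(graph, score, t).theta


def _weighted_tail_estimate(t, contrib, alpha, n, seed, method) -> TailEstimate:
    p_hat = float(contrib.mean())
    se = float(contrib.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    log_p = float(np.log(p_hat)) if p_hat > 0 else -np.inf
    return TailEstimate(
        threshold=float(t), log_p=log_p, method=method, theta_or_alpha=float(alpha),
        standard_error=se,
        ci_low=max(0.0, p_hat - 1.96 * se),
        ci_high=min(1.0, p_hat + 1.96 * se),
        n_samples=int(n),
    )


def importance_sample_tail(graph: FactorGraph, score: ScoreSpec, t: float,
                           alpha: float | None = None, n: int = 10_000, seed: int = 0,
                           return_batch: bool = False):
    """IS estimate of P(S > t) with exponential-tilt proposal P̃_α.

    ``alpha=None`` selects the saddlepoint-guided value θ(t); ``alpha=0`` is
    naive sampling.  Returns a :class:`TailEstimate` (and the
    :class:`SampleBatch` when ``return_batch``).
    """
    if n < 2:
        raise ValueError("sampling estimators need n >= 2")
    if alpha is None:
        alpha = saddlepoint_guided_alpha(graph, score, t)
    alpha = float(alpha)
    proposal = tilt(graph, score, alpha) if alpha != 0.0 else graph
    configs = forward_sample(proposal, n, seed)
    s = sample_scores(graph, score, configs)
    kappa_a = cgf_moments(graph, score, alpha).kappa if alpha != 0.0 else 0.0
    log_w = kappa_a - alpha * s
    contrib = np.where(s > t, np.exp(log_w), 0.0)
    method = "naive" if alpha == 0.0 else "importance"
    est = _weighted_tail_estimate(t, contrib, alpha, n, seed, method)
    if return_batch:
        return est, SampleBatch(s, log_w, alpha, seed, n)
    return est


def latent_statistic_tail(graph: FactorGraph, score: ScoreSpec, observed_vars, statistic,
                          t: float, alpha: float = 0.0, n: int = 10_000, seed: int = 0,
                          tail_side: str = "upper", return_batch: bool = False):
    """IS tail estimate for a statistic of the *observed* variables only.

    Full configurations are sampled from the tilted graph and weighted with
    the full-data weights exp(κ(α) − α S(x)); the statistic is evaluated on
    each sample's observed-variable restriction, which keeps the estimate
    unbiased even though the statistic itself (e.g. a posterior expectation
    given the observations) does not factorize over the graph.

    ``statistic`` maps an (n, n_observed) state array to n values; ``None``
    uses the posterior expected score given the observed states, memoized
    over distinct observation patterns.
    """
    observed_vars = list(observed_vars)
    alpha = float(alpha)
    proposal = tilt(graph, score, alpha) if alpha != 0.0 else graph
    configs = forward_sample(proposal, n, seed)
    obs_cols = [graph.var_index[v] for v in observed_vars]
    obs = configs[:, obs_cols]
    if statistic is None:
        uniq, inverse = np.unique(obs, axis=0, return_inverse=True)
        vals = np.array([
            posterior_expected_score(graph, score, dict(zip(observed_vars, (int(s) for s in row))))
            for row in uniq
        ])
        stat = vals[inverse]
    else:
        stat = np.asarray(statistic(obs), dtype=float)
        if stat.shape != (n,):
            raise ValueError("statistic must return one value per sample")
    s_full = sample_scores(graph, score, configs)
    kappa_a = cgf_moments(graph, score, alpha).kappa if alpha != 0.0 else 0.0
    log_w = kappa_a - alpha * s_full
    if tail_side == "upper":
        hit = stat > t
    elif tail_side == "lower":
        hit = stat < t
    else:
        raise ValueError("tail_side must be 'upper' or 'lower'")
    contrib = np.where(hit, np.exp(log_w), 0.0)
    method = "naive" if alpha == 0.0 else "importance"
    est = _weighted_tail_estimate(t, contrib, alpha, n, seed, method)
    if tail_side == "lower":
        est.flags.add("lower_tail")
    if return_batch:
        return est, SampleBatch(stat, log_w, alpha, seed, n)
    return est
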