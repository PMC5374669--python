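# fgsig — significance evaluation on tree factor graphs

`fgsig` computes the statistical significance of additive scores defined
over discrete, cycle-free factor graphs.  Given a null model

&nbsp;&nbsp;&nbsp;&nbsp;P(x) ∝ Π<sub>a∈𝒜</sub> f<sub>a</sub>(x<sub>a</sub>)

over variables with finite state spaces, and a score that decomposes over
the factors,

&nbsp;&nbsp;&nbsp;&nbsp;S(x) = Σ<sub>a∈𝒜</sub> g<sub>a</sub>(x<sub>a</sub>),

it estimates the tail probability z = P(S > t) — the p-value of an observed
score — with four methods:

- **naive sampling**: forward-sample the graph, count exceedances;
- **importance sampling (IS)**: sample the exponentially tilted graph
  f̃<sub>a,α</sub> = f<sub>a</sub>·exp(α g<sub>a</sub>), which has the same
  tree structure, and reweight by w = exp(κ(α) − αS).  The
  *saddlepoint-guided* choice α = θ(t) puts the proposal's mean score at
  the threshold and reaches p-values far below anything naive sampling can
  resolve;
- **normal approximation**: Φ̄((t − κ′(0))/√κ″(0));
- **saddlepoint approximation (SA)**: solve κ′(θ) = t and evaluate
  P(S > t) ≈ exp(κ(θ) − tθ + θ²v/2)·Φ̄(θ√v) with v = κ″(θ), optionally with
  a lattice correction for integer-valued scores.

The engine underneath is exact message passing: the cumulant generating
function κ(θ) = log E[e<sup>θS</sup>] and its first two derivatives are
computed *exactly* on the tilted graph by a single leaf-to-root pass of
moment triples (an expectation semiring), so SA and SG-IS cost no more than
a few sum-product sweeps even on graphs with 10⁵ factors.

Ready-made builders cover four standard applications:

| builder | model | use |
|---|---|---|
| `poisson_binomial_model` | independent Bernoulli events, optional weights | mutation-burden style tests |
| `pwm_model` | position weight matrix vs i.i.d. background | motif match p-values |
| `markov_model` | order-r Markov motif vs order-r background (compounded to a tree) | BaMM-style context-dependent motifs |
| `phylo_model` | Newick tree + JC69 substitution model | conservation / acceleration of alignment columns |

Exact oracles (exhaustive enumeration, convolution of independent score
distributions, closed-form binomial tails, CTMC path simulation) ship in
`fgsig.oracles` and back every estimator with an independent check.

## Worked example

One thousand heterogeneous Bernoulli events (success probabilities drawn
from Beta(1, 100), the classic heterogeneous-rate setting), scored by the
number of successes:

```python
import numpy as np
import fgsig as fg

rng = np.random.default_rng(42)
p = rng.beta(1, 100, 1000)                 # per-event success probabilities
graph, score = fg.poisson_binomial_model(p)

m, v = fg.score_mean_variance(graph, score)
print(f"E[S] = {m:.4f}, V[S] = {v:.4f}")

for t in (25, 30, 35):
    sa = fg.saddlepoint_tail(graph, score, t, lattice=1.0)
    print(f"t = {t}: SA p = {sa.p:.4e}  (theta = {sa.theta_or_alpha:.4f})")

est = fg.importance_sample_tail(graph, score, 30, n=10_000, seed=0)
print(f"SG-IS at t = 30: p = {est.p:.4e} +- {est.standard_error:.1e}")
```

prints

```
E[S] = 10.2617, V[S] = 10.0529
t = 25: SA p = 2.1141e-05  (theta = 0.9615)
t = 30: SA p = 9.0534e-08  (theta = 1.1475)
t = 35: SA p = 1.7053e-10  (theta = 1.3072)
SG-IS at t = 30: p = 8.7249e-08 +- 2.3e-09
```

The mean count is ~10.3; observing 30 successes has p ≈ 9·10⁻⁸.  The two
independent routes — analytic saddlepoint and tilted sampling — agree to
within the sampling standard error, and both are far beyond the reach of
naive simulation (which would need ~10⁹ draws for a single hit).  `theta`
is the tilting parameter at which the tilted mean equals each threshold;
`lattice=1.0` declares that the score lives on the integers, which sharpens
the saddlepoint tail to sub-percent accuracy.

The same computations are available from the shell:

```sh
$ fgsig pb --p 0.1,0.2,0.3,0.1,0.2 --method sa --lattice 1 -t 2.5
threshold  method       p                     log10_p   theta_or_alpha  ...
2.5        saddlepoint  0.037376734615913662  -1.427...  2.036...       lattice_corrected
$ fgsig pb --p 0.1,0.2,0.3,0.1,0.2 --method exact -t 2.5
2.5        exact        0.039720000000000012  -1.400...
```

Subcommands: `pvalue` (generic graph-spec files), `pb`, `pwm` (JASPAR flat
format, with `--scan-length` for scan-maximum significance), `markov`,
`phylo` (Newick trees, conservation p-values for alignment columns) and
`sample`.

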