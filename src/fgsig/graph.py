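"""Discrete factor graphs on trees.

A factor graph is a bipartite graph of variable nodes (finite state spaces)
and factor nodes (non-negative potential tables over their scopes).  The
joint measure is P(x) ∝ Π_a f_a(x_a); it need not be normalized — every
probabilistic quantity downstream is defined relative to the partition
function Z.  Only cycle-free (forest) structures are accepted, which is what
makes exact message passing possible.

Conventions: state indexing is 0-based; potential tables are laid out
row-major with the *last* scope variable varying fastest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Evidence",
    "Variable",
    "Factor",
    "FactorGraph",
    "GraphStructureError",
    "build_factor_graph",
    "set_evidence",
    "is_normalized",
]


#: Observed-variable clamping: variable identifier -> observed state index.
Evidence = Mapping[str, int]


class GraphStructureError(ValueError):
    """Raised when a graph definition violates a structural invariant."""


@dataclass(frozen=True)
class Variable:
    name: str
    n_states: int


@dataclass
class Factor:
    """A factor with an ordered scope and a potential table.

    ``log_potential`` is the canonical internal representation (zero entries
    map to −inf); ``potential`` preserves the caller's linear-domain table
    for lossless round-tripping through the interchange format.
    """

    name: str
    scope: tuple[str, ...]
    potential: np.ndarray
    log_potential: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.log_potential is None:
            with np.errstate(divide="ignore", invalid="ignore"):
                object.__setattr__(self, "log_potential", np.log(self.potential))


class FactorGraph:
    """Validated tree-structured factor graph.

    Use :func:`build_factor_graph` rather than constructing directly.
    """

    def __init__(self, variables: Sequence[Variable], factors: Sequence[Factor],
                 _validate: bool = True):
        self.variables = list(variables)
        self.factors = list(factors)
        self.var_index = {v.name: i for i, v in enumerate(self.variables)}
        self.factor_index = {f.name: i for i, f in enumerate(self.factors)}
        # adjacency: variable name -> factor indices, declaration order
        self.var_factors: dict[str, list[int]] = {v.name: [] for v in self.variables}
        for j, f in enumerate(self.factors):
            for name in f.scope:
                if name in self.var_factors:
                    self.var_factors[name].append(j)
        self._cache: dict = {}
        if _validate:
            self._validate()

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        if len(self.var_index) != len(self.variables):
            raise GraphStructureError("duplicate variable identifiers")
        if len(self.factor_index) != len(self.factors):
            raise GraphStructureError("duplicate factor identifiers")
        for v in self.variables:
            if v.n_states < 1:
                raise GraphStructureError(f"variable {v.name!r} has cardinality {v.n_states}")
        for f in self.factors:
            if len(f.scope) == 0:
                raise GraphStructureError(f"factor {f.name!r} has empty scope (arity-0 factors are rejected)")
            if len(set(f.scope)) != len(f.scope):
                raise GraphStructureError(f"factor {f.name!r} repeats a variable in its scope")
            for name in f.scope:
                if name not in self.var_index:
                    raise GraphStructureError(f"factor {f.name!r} references undeclared variable {name!r}")
            expected = tuple(self.variables[self.var_index[n]].n_states for n in f.scope)
            if f.potential.shape != expected:
                raise GraphStructureError(
                    f"factor {f.name!r}: potential shape {f.potential.shape} != scope shape {expected}")
            if np.any(np.isnan(f.potential)):
                raise GraphStructureError(f"factor {f.name!r} contains NaN")
            neg = np.argwhere(f.potential < 0)
            if neg.size:
                idx = tuple(int(i) for i in neg[0])
                raise GraphStructureError(f"factor {f.name!r} has negative entry at index {idx}")
            if not np.any(f.potential > 0):
                raise GraphStructureError(f"factor {f.name!r} has no strictly positive entry")
        for v in self.variables:
            if not self.var_factors[v.name]:
                raise GraphStructureError(f"variable {v.name!r} appears in no factor scope")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # union-find over variable and factor nodes; a repeated root means a cycle
        n_var = len(self.variables)
        parent = list(range(n_var + len(self.factors)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for j, f in enumerate(self.factors):
            fj = n_var + j
            for name in f.scope:
                vi = self.var_index[name]
                ra, rb = find(vi), find(fj)
                if ra == rb:
                    raise GraphStructureError(
                        f"cycle detected through edge ({name!r}, factor {f.name!r})")
                parent[ra] = rb

    # -- convenience --------------------------------------------------------

    def cardinality(self, name: str) -> int:
        return self.variables[self.var_index[name]].n_states

    @property
    def n_configurations(self) -> int:
        n = 1
        for v in self.variables:
            n *= v.n_states
        return n

    def copy_with_log_potentials(self, log_potentials: Sequence[np.ndarray]) -> "FactorGraph":
        """Same structure with replaced potentials (log domain); skips re-validation."""
        with np.errstate(over="ignore"):
            factors = [Factor(f.name, f.scope, np.exp(lp), lp)
                       for f, lp in zip(self.factors, log_potentials)]
        return FactorGraph(self.variables, factors, _validate=False)


def build_factor_graph(
    variables: Iterable[tuple[str, int] | Variable],
    factors: Iterable[tuple[str, Sequence[str], np.ndarray] | Factor],
) -> FactorGraph:
    """Build and validate a tree factor graph.

    Parameters
    ----------
    variables:
        ``(name, n_states)`` pairs in declaration order.
    factors:
        ``(name, scope, potential)`` triples; ``potential`` must have one
        axis per scope variable, in scope order.
    """
    vs = [v if isinstance(v, Variable) else Variable(str(v[0]), int(v[1])) for v in variables]
    fs = []
    for f in factors:
        if isinstance(f, Factor):
            fs.append(f)
        else:
            name, scope, pot = f
            fs.append(Factor(str(name), tuple(scope), np.asarray(pot, dtype=float)))
    return FactorGraph(vs, fs)


def set_evidence(graph: FactorGraph, evidence: Mapping[str, int]) -> FactorGraph:
    """Clamp observed variables to their observed states.

    Every factor adjacent to an observed variable has the complementary
    slices of its potential zeroed; the structure (and therefore any
    shape-matched ScoreSpec) is unchanged.  Idempotent, and commutes across
    disjoint evidence sets.
    """
    for name, state in evidence.items():
        if name not in graph.var_index:
            raise KeyError(f"evidence references unknown variable {name!r}")
        card = graph.cardinality(name)
        if not 0 <= int(state) < card:
            raise ValueError(f"evidence state {state} out of range for {name!r} (cardinality {card})")
    log_pots = []
    for f in graph.factors:
        lp = f.log_potential
        touched = False
        for axis, name in enumerate(f.scope):
            if name in evidence:
                if not touched:
                    lp = lp.copy()
                    touched = True
                keep = int(evidence[name])
                sl = [slice(None)] * lp.ndim
                for s in range(lp.shape[axis]):
                    if s != keep:
                        sl[axis] = s
                        lp[tuple(sl)] = -np.inf
        log_pots.append(lp)
    return graph.copy_with_log_potentials(log_pots)


def is_normalized(graph: FactorGraph, tolerance: float = 1e-9) -> bool:
    """True iff the partition function satisfies |Z − 1| ≤ tolerance."""
    from .inference import sum_product

    return bool(abs(np.expm1(sum_product(graph).log_Z)) <= tolerance)
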