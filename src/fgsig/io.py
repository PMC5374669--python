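"""Readers and writers: the YAML/JSON graph-spec interchange format,
JASPAR flat-format position frequency matrices, and TSV probability tables.

Graph-spec layout (documented, fixed field names)::

    variables:
      - {name: x1, states: 2}
    factors:
      - {name: a, scope: [x1], potential: [0.7, 0.3]}
    scores:            # optional, one flat table per factor, same order
      - [0.0, 1.0]

Flat tables are row-major with the *last* scope variable varying fastest;
round-trips are bit-exact (floats serialized via repr).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import yaml

from .graph import FactorGraph, build_factor_graph
from .scoring import ScoreSpec

__all__ = [
    "read_graph_spec",
    "write_graph_spec",
    "read_jaspar_pfm",
    "read_table",
]


class SchemaError(ValueError):
    """A graph-spec document violates the interchange schema."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise SchemaError(msg)


def read_graph_spec(path) -> tuple[FactorGraph, ScoreSpec | None]:
    doc = yaml.safe_load(Path(path).read_text())
    _require(isinstance(doc, dict), "top level must be a mapping")
    _require("variables" in doc, "missing 'variables'")
    _require("factors" in doc, "missing 'factors'")
    variables = []
    for i, v in enumerate(doc["variables"]):
        _require(isinstance(v, dict) and "name" in v, f"variable #{i} missing 'name'")
        _require("states" in v, f"variable {v.get('name', i)!r} missing 'states'")
        variables.append((str(v["name"]), int(v["states"])))
    cards = dict(variables)
    factors = []
    for i, f in enumerate(doc["factors"]):
        _require(isinstance(f, dict) and "name" in f, f"factor #{i} missing 'name'")
        for key in ("scope", "potential"):
            _require(key in f, f"factor {f.get('name', i)!r} missing {key!r}")
        scope = [str(s) for s in f["scope"]]
        for s in scope:
            _require(s in cards, f"factor {f['name']!r} scope references unknown variable {s!r}")
        shape = tuple(cards[s] for s in scope)
        flat = np.asarray(f["potential"], dtype=float)
        _require(flat.size == int(np.prod(shape)),
                 f"factor {f['name']!r}: potential has {flat.size} entries, expected {int(np.prod(shape))}")
        factors.append((f["name"], scope, flat.reshape(shape)))
    graph = build_factor_graph(variables, factors)
    score = None
    if doc.get("scores") is not None:
        _require(len(doc["scores"]) == len(factors),
                 f"'scores' must list one table per factor ({len(factors)})")
        tables = []
        for (name, scope, pot), flat in zip(factors, doc["scores"]):
            arr = np.asarray(flat, dtype=float)
            _require(arr.size == pot.size, f"score table for factor {name!r} has wrong length")
            tables.append(arr.reshape(pot.shape))
        score = ScoreSpec(graph, tables)
    return graph, score


def write_graph_spec(graph: FactorGraph, path, score: ScoreSpec | None = None) -> None:
    doc: dict = {
        "variables": [{"name": v.name, "states": v.n_states} for v in graph.variables],
        "factors": [{"name": f.name, "scope": list(f.scope),
                     "potential": [float(x) for x in f.potential.ravel()]}
                    for f in graph.factors],
    }
    if score is not None:
        doc["scores"] = [[float(x) for x in t.ravel()] for t in score.tables]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


_JASPAR_ROW = re.compile(r"^\s*([ACGT])\s*\[?\s*([-\d.eE+\s]*?)\s*\]?\s*$")


def read_jaspar_pfm(path) -> tuple[np.ndarray, str]:
    """Parse a JASPAR flat-format PFM: '>ID name' header then rows
    'A [ 4 12 0 ... ]' (brackets optional).  Returns (4×N counts, identifier)."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty PFM file")
    ident = "motif"
    if lines[0].startswith(">"):
        ident = lines[0][1:].strip().split()[0] if lines[0][1:].strip() else "motif"
        lines = lines[1:]
    rows: dict[str, np.ndarray] = {}
    for ln in lines:
        m = _JASPAR_ROW.match(ln)
        if m is None:
            raise ValueError(f"unrecognized PFM row: {ln!r}")
        base, payload = m.group(1), m.group(2)
        rows[base] = np.array([float(x) for x in payload.split()])
    missing = [b for b in "ACGT" if b not in rows]
    if missing:
        raise ValueError(f"PFM missing rows for {missing}")
    lengths = {rows[b].size for b in "ACGT"}
    if len(lengths) != 1:
        raise ValueError("PFM rows have unequal lengths")
    counts = np.vstack([rows[b] for b in "ACGT"])
    if np.any(counts < 0):
        raise ValueError("PFM contains negative entries")
    return counts, ident


def read_table(path) -> np.ndarray:
    """Whitespace/tab-separated numeric table (comments with '#')."""
    return np.atleast_2d(np.loadtxt(path, comments="#", dtype=float))
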