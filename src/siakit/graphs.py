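"""Pair classification and directed implication graphs.

The graph view of an implication analysis has one node per outcome and a
directed edge for every significant implication with positive index;
significant *negative* indices (evidence against an implication) are kept in
tabular results but never drawn as edges. Each unordered pair is classified
as reciprocal (both directions are significant positive implications),
forward-only, backward-only, or none.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum

import networkx as nx

from .inference import ImplicationResult

__all__ = ["PairCategory", "PairClassification", "classify_pairs",
           "build_graph", "export_graph"]


class PairCategory(str, Enum):
    RECIPROCAL = "reciprocal"
    FORWARD_ONLY = "forward_only"
    BACKWARD_ONLY = "backward_only"
    NONE = "none"


@dataclass(frozen=True)
class PairClassification:
    """Classification of one unordered outcome pair.

    ``forward`` is the result for (first, second) and ``backward`` for
    (second, first), where (first, second) is the lexicographically sorted
    pair — the category is therefore independent of input order.
    """

    first: str
    second: str
    category: PairCategory
    forward: ImplicationResult
    backward: ImplicationResult


def _is_positive_implication(r: ImplicationResult) -> bool:
    return r.significant and r.iota > 0


def classify_pairs(results: list[ImplicationResult]) -> list[PairClassification]:
    """Classify every unordered pair present in the results.

    Requires both directions of each pair (as produced by an all-pairs
    analysis) and a single stratum; raises otherwise, naming the pair.
    """
    strata = {r.stratum for r in results}
    if len(strata) > 1:
        raise ValueError(f"results mix strata {sorted(map(str, strata))}; classify per stratum")
    by_pair: dict[tuple[str, str], ImplicationResult] = {}
    for r in results:
        by_pair[(r.source, r.target)] = r
    out = []
    seen = set()
    for (s, t) in sorted(by_pair):
        key = tuple(sorted((s, t)))
        if key in seen:
            continue
        seen.add(key)
        first, second = key
        fwd = by_pair.get((first, second))
        bwd = by_pair.get((second, first))
        if fwd is None or bwd is None:
            raise ValueError(f"missing direction for pair ({first}, {second})")
        f_pos = _is_positive_implication(fwd)
        b_pos = _is_positive_implication(bwd)
        if f_pos and b_pos:
            cat = PairCategory.RECIPROCAL
        elif f_pos:
            cat = PairCategory.FORWARD_ONLY
        elif b_pos:
            cat = PairCategory.BACKWARD_ONLY
        else:
            cat = PairCategory.NONE
        out.append(PairClassification(first, second, cat, fwd, bwd))
    return out


def build_graph(results: list[ImplicationResult]) -> nx.DiGraph:
    """Directed implication graph: significant positive results as edges.

    All outcomes appearing in the results become nodes, so outcomes without
    any significant implication stay visible as isolated nodes. Edge
    attributes: ``iota``, ``ci_low``, ``ci_high``.
    """
    g = nx.DiGraph()
    for r in results:
        g.add_node(r.source)
        g.add_node(r.target)
    for r in results:
        if _is_positive_implication(r):
            g.add_edge(r.source, r.target,
                       iota=r.iota, ci_low=r.ci_low, ci_high=r.ci_high)
    return g


def _dot_quote(name: str) -> str:
    return '"' + name.replace('"', r'\"') + '"'


def export_graph(g: nx.DiGraph, fmt: str = "dot") -> str:
    """Serialize an implication graph as DOT or JSON text.

    DOT edges carry the label ``iota=<value> [<ci_low>, <ci_high>]`` with
    three decimals; the JSON form has a ``nodes`` array and an ``edges``
    array of ``{source, target, iota, ci_low, ci_high}`` objects.
    """
    if fmt == "dot":
        lines = ["digraph implications {"]
        for node in sorted(g.nodes):
            lines.append(f"  {_dot_quote(node)};")
        for s, t, attrs in sorted(g.edges(data=True)):
            label = (f"ι={attrs['iota']:.3f} "
                     f"[{attrs['ci_low']:.3f}, {attrs['ci_high']:.3f}]")
            lines.append(f"  {_dot_quote(s)} -> {_dot_quote(t)} [label=\"{label}\"];")
        lines.append("}")
        return "\n".join(lines) + "\n"
    if fmt == "json":
        payload = {
            "nodes": sorted(g.nodes),
            "edges": [
                {"source": s, "target": t, "iota": attrs["iota"],
                 "ci_low": attrs["ci_low"], "ci_high": attrs["ci_high"]}
                for s, t, attrs in sorted(g.edges(data=True))
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"
    raise ValueError(f"unknown graph format {fmt!r}; expected 'dot' or 'json'")
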