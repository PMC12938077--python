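"""Junction-level stacking reconstruction by matching on a cycle graph.

Stems of an n-way junction are the vertices of a cycle graph whose edges
are the cyclically adjacent stem pairs, weighted by the classifier's
stacking probabilities.  Edges at or below the decision threshold are
discarded, and the stacking configuration is the maximum-weight matching
of the retained edges: the set of non-conflicting stem-stem stacks with
the largest total probability (each stem stacks with at most one partner).

The matching is solved exactly by dynamic programming on the cycle
(conditioning on whether the wrap-around edge is selected, then solving
two path problems); a brute-force enumerator over all matchings serves as
an independent oracle.  For n = 2 the cycle degenerates to one candidate
edge and the outcome is binary.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

__all__ = [
    "CycleGraph",
    "Matching",
    "StackingConfiguration",
    "DEFAULT_THRESHOLD",
    "cycle_edges",
    "build_cycle_graph",
    "max_weight_matching_cycle",
    "brute_force_matching",
    "enumerate_configurations",
    "configuration_label",
]

DEFAULT_THRESHOLD = 0.42  # shipped decision threshold (KDE crossing of the reference model)


def cycle_edges(order_n: int) -> list[tuple[int, int]]:
    """Candidate adjacent stem pairs of an order-n junction (1 for n=2, n for n>=3)."""
    if order_n < 2:
        raise ValueError("junction order must be >= 2")
    if order_n == 2:
        return [(0, 1)]
    return [(i, (i + 1) % order_n) for i in range(order_n)]


@dataclass(frozen=True)
class CycleGraph:
    """Cycle graph of one junction: all candidate edges plus the retained subset."""

    order_n: int
    weights: dict[tuple[int, int], float]
    retained: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        expected = set(cycle_edges(self.order_n))
        if set(self.weights) != expected:
            raise ValueError("weights must cover every cyclically adjacent pair exactly once")
        if not self.retained <= expected:
            raise ValueError("retained edges must be candidate edges")
        for w in self.weights.values():
            if not 0.0 <= w <= 1.0:
                raise ValueError("edge weights must be probabilities in [0, 1]")


@dataclass(frozen=True)
class Matching:
    """A vertex-disjoint edge subset and its total weight."""

    selected_edges: tuple[tuple[int, int], ...]
    total_weight: float

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for u, v in self.selected_edges:
            if u in seen or v in seen:
                raise ValueError("matching edges share a vertex")
            seen.update((u, v))


@dataclass(frozen=True)
class StackingConfiguration:
    """Junction-level assignment of stacked stem pairs (prediction or truth)."""

    junction_id: str
    order_n: int
    stacked_pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        allowed = set(cycle_edges(self.order_n))
        if not self.stacked_pairs <= allowed:
            raise ValueError("stacked pairs must be cyclically adjacent stem pairs")
        Matching(tuple(sorted(self.stacked_pairs)), 0.0)  # vertex-disjointness check


def build_cycle_graph(
    predictions: Sequence,
    threshold: float = DEFAULT_THRESHOLD,
    order_n: Optional[int] = None,
) -> CycleGraph:
    """Assemble the cycle graph from one junction's pairwise predictions.

    ``predictions`` must cover every cyclically adjacent pair exactly once,
    as objects with ``stem_pair`` and ``probability`` attributes or as
    ``((i, j), p)`` tuples.  Only edges with probability strictly above
    ``threshold`` are retained.
    """
    weights: dict[tuple[int, int], float] = {}
    for pred in predictions:
        if hasattr(pred, "stem_pair"):
            edge, p = tuple(pred.stem_pair), float(pred.probability)
        else:
            edge, p = tuple(pred[0]), float(pred[1])
        if edge in weights:
            raise ValueError(f"duplicate prediction for pair {edge}")
        weights[edge] = p
    if order_n is None:
        order_n = 2 if len(weights) == 1 else len(weights)
    expected = set(cycle_edges(order_n))
    if set(weights) != expected:
        missing = expected - set(weights)
        raise ValueError(f"predictions missing pairs {sorted(missing)}")
    retained = frozenset(e for e, p in weights.items() if p > threshold)
    return CycleGraph(order_n=order_n, weights=weights, retained=retained)


# Tie-break among equal-weight matchings: fewer edges first, then
# lexicographically smallest sorted edge tuple.  Encoded as a sort key on
# (weight, -len, reversed-lex) maximization via the helper below.
def _key(total: float, edges: tuple[tuple[int, int], ...]):
    return (total, -len(edges), tuple(-u * 10_000 - v for u, v in edges))


def _best_path(edge_list: list[tuple[tuple[int, int], float]]) -> tuple[float, tuple]:
    """Maximum-weight matching on a path of sequential edges (DP).

    ``edge_list`` holds (edge, weight) for consecutive edges e_k joining
    vertices v_k, v_k+1; an omitted (non-retained) edge is passed as weight
    None and can never be selected.
    """
    # f[k]: best over first k edges; g = f[k-1], h = f[k-2]
    h = (0.0, ())
    g = (0.0, ())
    for k, (edge, w) in enumerate(edge_list):
        if w is None:
            nxt = g
        else:
            take = (h[0] + w, h[1] + (edge,))
            nxt = max(g, take, key=lambda s: _key(*s))
        h, g = g, nxt
    return g


def max_weight_matching_cycle(graph: CycleGraph) -> Matching:
    """Exact maximum-weight matching of the retained cycle edges.

    Splits on whether the wrap-around edge (s_n, s_1) is selected: if not,
    the problem is a path DP over the remaining edges; if selected, its two
    neighboring edges are excluded and a shorter path DP covers the rest.
    Deterministic tie-break: fewer edges, then lexicographically smallest.
    """
    n = graph.order_n
    edges = cycle_edges(n)
    wts = [graph.weights[e] if e in graph.retained else None for e in edges]
    if n == 2:
        (edge,) = edges
        if wts[0] is None:
            return Matching((), 0.0)
        return Matching((edge,), wts[0])
    # case A: wrap edge excluded
    best = _best_path(list(zip(edges[:-1], wts[:-1])))
    # case B: wrap edge selected (excludes first and last path edges)
    if wts[-1] is not None:
        inner = _best_path(list(zip(edges[1:-2], wts[1:-2])))
        with_wrap = (inner[0] + wts[-1], inner[1] + (edges[-1],))
        best = max(best, with_wrap, key=lambda s: _key(*s))
    selected = tuple(sorted(best[1]))
    return Matching(selected_edges=selected, total_weight=best[0])


def brute_force_matching(graph: CycleGraph, max_order: int = 20) -> Matching:
    """Exhaustive matching oracle (same tie-break as the DP)."""
    if graph.order_n > max_order:
        raise ValueError(f"brute force limited to order <= {max_order}")
    retained = sorted(graph.retained)
    best = (0.0, ())
    for r in range(len(retained) + 1):
        for subset in combinations(retained, r):
            seen: set[int] = set()
            ok = True
            for u, v in subset:
                if u in seen or v in seen:
                    ok = False
                    break
                seen.update((u, v))
            if not ok:
                continue
            total = sum(graph.weights[e] for e in subset)
            cand = (total, tuple(sorted(subset)))
            best = max(best, cand, key=lambda s: _key(*s))
    return Matching(selected_edges=best[1], total_weight=best[0])


def enumerate_configurations(order_n: int) -> list[StackingConfiguration]:
    """Every possible stacking configuration (matching) of an order-n junction.

    Counts follow the cycle-matching recurrence (Lucas numbers) for n >= 3:
    4 configurations for three-way and 7 for four-way junctions; a two-way
    junction is binary (stacked / unstacked).
    """
    if not 2 <= order_n <= 12:
        raise ValueError("order must be in [2, 12]")
    edges = cycle_edges(order_n)
    configs: list[StackingConfiguration] = []
    for r in range(len(edges) + 1):
        for subset in combinations(edges, r):
            seen: set[int] = set()
            if any(u in seen or v in seen or seen.update((u, v)) for u, v in subset):
                continue
            configs.append(
                StackingConfiguration(
                    junction_id=f"order{order_n}",
                    order_n=order_n,
                    stacked_pairs=frozenset(subset),
                )
            )
    return configs


def configuration_label(config: StackingConfiguration) -> str:
    """Human-readable configuration name, e.g. ``"H1-H2+H3-H4"`` or ``"none"``."""
    if not config.stacked_pairs:
        return "none"
    return "+".join(f"H{u + 1}-H{v + 1}" for u, v in sorted(config.stacked_pairs))
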