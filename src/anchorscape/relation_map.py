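"""Variant relation graphs: linking anchors that differ at few residues.

Nodes are distinct genotypes; an edge joins two genotypes whose sequences
differ at 1..max_distance residues.  With ``max_distance=2`` this is the
"fewer than 3 amino-acid differences" rule; ``max_distance=1`` gives the
stricter "fewer than 2" linkage used for tree-overlay curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import networkx as nx

from .variants import AnchorSet, Variant, variant_distance


@dataclass(frozen=True)
class EvolutionPath:
    """An ordered walk from source to target through graph-adjacent variants."""

    variants: tuple[Variant, ...]
    step_distances: tuple[int, ...]
    fitnesses: tuple[float, ...]

    def labels(self) -> tuple[str, ...]:
        return tuple(v.label() for v in self.variants)


@dataclass(frozen=True)
class PeakComponent:
    """One connected component of the high-fitness subgraph."""

    members: tuple[str, ...]
    size: int
    peak_variant: str
    peak_fitness: float


def build_relation_graph(s: AnchorSet, max_distance: int = 2) -> nx.Graph:
    """Graph over distinct genotypes; edge iff 1 <= distance <= max_distance.

    Node keys are canonical variant labels; node attributes carry the
    Variant, mutation count, fitness (replicates geometric-mean combined)
    and log10 fitness.
    """
    if len(s) == 0:
        raise ValueError("anchor set is empty")
    if max_distance < 1:
        raise ValueError("max_distance must be >= 1")
    fmap = s.fitness_map()
    g = nx.Graph()
    nodes: list[tuple[str, Variant]] = []
    for muts, fit in fmap.items():
        v = Variant(muts, s.reference_id)
        g.add_node(v.label(), variant=v, n_mutations=v.n_mutations,
                   fitness=fit, log10_fitness=math.log10(fit))
        nodes.append((v.label(), v))
    for (la, va), (lb, vb) in combinations(nodes, 2):
        d = variant_distance(va, vb)
        if 1 <= d <= max_distance:
            g.add_edge(la, lb, distance=d)
    return g


def find_evolution_paths(
    g: nx.Graph,
    source: Variant,
    target: Variant,
    max_paths: int = 10,
    require_nondecreasing: bool = True,
) -> list[EvolutionPath]:
    """Up to ``max_paths`` simple paths source→target.

    By default paths must have non-decreasing mutation count along the way
    (mutations accumulate under segmented scanning; reversions are rare).
    Ordered by length then lexicographic label sequence.
    """
    src, tgt = source.label(), target.label()
    for lbl in (src, tgt):
        if lbl not in g:
            raise ValueError(f"variant {lbl!r} not in graph")
    paths = []
    for p in nx.all_simple_paths(g, src, tgt):
        counts = [g.nodes[n]["n_mutations"] for n in p]
        if require_nondecreasing and any(b < a for a, b in zip(counts, counts[1:])):
            continue
        paths.append(p)
    paths.sort(key=lambda p: (len(p), tuple(p)))
    out = []
    for p in paths[:max_paths]:
        variants = tuple(g.nodes[n]["variant"] for n in p)
        dists = tuple(g.edges[a, b]["distance"] for a, b in zip(p, p[1:]))
        fits = tuple(g.nodes[n]["fitness"] for n in p)
        out.append(EvolutionPath(variants, dists, fits))
    return out


def shared_peak_report(g: nx.Graph, fitness_threshold: float) -> list[PeakComponent]:
    """Connected components of the subgraph with fitness >= threshold.

    Several anchors clustering into one high-fitness component is the
    graph-level signature of a shared local peak in the landscape.
    """
    if fitness_threshold <= 0:
        raise ValueError("fitness threshold must be positive")
    keep = [n for n, d in g.nodes(data=True) if d["fitness"] >= fitness_threshold]
    sub = g.subgraph(keep)
    comps = []
    for comp in nx.connected_components(sub):
        members = tuple(sorted(comp))
        peak = max(members, key=lambda n: (g.nodes[n]["fitness"], n))
        comps.append(PeakComponent(members, len(members), peak,
                                   g.nodes[peak]["fitness"]))
    comps.sort(key=lambda c: (-c.peak_fitness, c.members))
    return comps
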