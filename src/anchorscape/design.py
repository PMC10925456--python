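"""Combinatorial design enumeration, model ranking and compression metrics.

Given a candidate-mutation list, :func:`enumerate_designs` traverses every
site-consistent combination of exactly k mutations; :func:`rank_designs`
scores them with a trained fitness model; :func:`compression_report`
quantifies how a handful of anchors compresses the theoretical design
space alphabet^sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .model import FitnessModel
from .variants import Mutation, Variant


@dataclass(frozen=True)
class DesignSpec:
    """Exactly-k combinatorial designs over a candidate mutation list."""

    candidates: tuple[Mutation, ...]
    k: int
    include_wildtype: bool = False
    reference_id: str = "ref"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if len(set(self.candidates)) != len(self.candidates):
            raise ValueError("duplicate candidate mutations")
        n_sites = len({m.site for m in self.candidates})
        if self.k > n_sites:
            raise ValueError(
                f"k={self.k} exceeds the {n_sites} distinct candidate sites")


def enumerate_designs(spec: DesignSpec) -> list[Variant]:
    """All exactly-k site-consistent candidate combinations.

    Deterministically ordered (lexicographic by variant label); wild type
    appended last when the flag is set.
    """
    out = []
    for combo in combinations(spec.candidates, spec.k):
        sites = [m.site for m in combo]
        if len(set(sites)) != len(sites):
            continue
        out.append(Variant(frozenset(combo), spec.reference_id))
    out.sort(key=lambda v: v.label())
    if spec.include_wildtype:
        out.append(Variant(frozenset(), spec.reference_id))
    return out


def count_designs(spec: DesignSpec) -> int:
    """Closed-form design count (equals ``len(enumerate_designs(spec))``).

    Sum over k-subsets of sites of the product of per-site option counts —
    the coefficient of x^k in prod_s (1 + c_s x) — plus 1 for wild type
    when included.
    """
    per_site: dict[int, int] = {}
    for m in spec.candidates:
        per_site[m.site] = per_site.get(m.site, 0) + 1
    # elementary symmetric polynomial via DP
    coeffs = [1] + [0] * spec.k
    for c in per_site.values():
        for j in range(spec.k, 0, -1):
            coeffs[j] += c * coeffs[j - 1]
    return coeffs[spec.k] + (1 if spec.include_wildtype else 0)


def rank_designs(model: FitnessModel, designs: Sequence[Variant],
                 top_n: int | None = None) -> list[tuple[Variant, float]]:
    """Designs sorted by predicted score, descending; ties lexicographic."""
    if not designs:
        return []
    scores = model.predict(designs)
    ranked = sorted(zip(designs, scores),
                    key=lambda vs: (-vs[1], vs[0].label()))
    if top_n is not None:
        ranked = ranked[:top_n]
    return [(v, float(s)) for v, s in ranked]


@dataclass(frozen=True)
class CompressionReport:
    """Design-space size vs anchor count, in log10 and floored exponents."""

    n_sites: int
    alphabet: int
    n_anchors: int
    space_size_log10: float
    ratio_log10: float
    space_exponent: int
    ratio_exponent: int


def compression_report(n_sites: int, alphabet: int = 20,
                       n_anchors: int = 1) -> CompressionReport:
    """alphabet^sites design-space size against the anchors that cover it.

    Exponents are floor(log10 ...), matching the truncated ``~10^N`` style
    of reporting.
    """
    if n_sites < 1 or alphabet < 1 or n_anchors < 1:
        raise ValueError("all counts must be >= 1")
    space = n_sites * math.log10(alphabet)
    ratio = space - math.log10(n_anchors)
    return CompressionReport(
        n_sites=n_sites, alphabet=alphabet, n_anchors=n_anchors,
        space_size_log10=space, ratio_log10=ratio,
        space_exponent=math.floor(space), ratio_exponent=math.floor(ratio))
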