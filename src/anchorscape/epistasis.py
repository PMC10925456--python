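"""Pairwise/group epistasis: the ε statistic and its sign classification.

For a background genotype g and two disjoint mutation groups A and B with
fitness values f_bg = f(g), f_a = f(g∪A), f_b = f(g∪B), f_ab = f(g∪A∪B):

    ε = f_bg + f_ab − f_a − f_b

ε > 0 is positive epistasis, ε < 0 negative.  Sign classification compares
the effect of each group with and without the other (ΔA = f_a − f_bg vs
ΔA|B = f_ab − f_b): *magnitude* epistasis leaves both signs unchanged,
*sign* epistasis flips exactly one, *reciprocal sign* epistasis flips both.
Effects within the tolerance of zero are treated as sign-neutral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

from .variants import AnchorSet, Mutation, Variant

EPISTASIS_CLASSES = ("none", "magnitude", "sign", "reciprocal_sign")


@dataclass(frozen=True)
class EpistasisQuery:
    """A (background, group A, group B) decomposition to evaluate."""

    background: Variant
    group_a: frozenset[Mutation]
    group_b: frozenset[Mutation]

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ValueError("mutation groups must be nonempty")
        bg = self.background.mutations
        if (self.group_a & bg) or (self.group_b & bg) or (self.group_a & self.group_b):
            raise ValueError("background, group A and group B must be disjoint")
        # all four genotypes must be site-consistent
        for muts in (bg | self.group_a, bg | self.group_b,
                     bg | self.group_a | self.group_b):
            Variant(frozenset(muts), self.background.reference_id)

    def genotypes(self) -> tuple[frozenset[Mutation], ...]:
        """(g, g∪A, g∪B, g∪A∪B) as mutation sets."""
        bg = self.background.mutations
        return (bg, bg | self.group_a, bg | self.group_b,
                bg | self.group_a | self.group_b)

    def label(self) -> str:
        def grp(ms: frozenset[Mutation]) -> str:
            return "+".join(str(m) for m in sorted(ms, key=lambda m: (m.site, m.mut_aa)))

        return f"bg={self.background.label()} A=[{grp(self.group_a)}] B=[{grp(self.group_b)}]"


@dataclass(frozen=True)
class EpistasisResult:
    epsilon: float
    effect_a_in_bg: float
    effect_a_with_b: float
    effect_b_in_bg: float
    effect_b_with_a: float
    klass: str
    tolerance: float
    query: EpistasisQuery | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.klass not in EPISTASIS_CLASSES:
            raise ValueError(f"unknown class {self.klass!r}")


def epistasis_value(f_bg: float, f_a: float, f_b: float, f_ab: float) -> float:
    """ε = f_bg + f_ab − f_a − f_b (positive ε: positive epistasis)."""
    for f in (f_bg, f_a, f_b, f_ab):
        if f is None or not math.isfinite(f):
            raise ValueError("all four fitness values must be finite")
    return f_bg + f_ab - f_a - f_b


def _sign_flips(eff_alone: float, eff_with: float, tolerance: float) -> bool:
    # strict flip: product negative AND both magnitudes beyond tolerance
    return (eff_alone * eff_with < 0
            and abs(eff_alone) > tolerance
            and abs(eff_with) > tolerance)


def classify_epistasis(
    f_bg: float,
    f_a: float,
    f_b: float,
    f_ab: float,
    tolerance: float = 0.0,
    query: EpistasisQuery | None = None,
) -> EpistasisResult:
    """Classify a fitness quadruple as none/magnitude/sign/reciprocal_sign."""
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    eps = epistasis_value(f_bg, f_a, f_b, f_ab)
    d_a, d_a_b = f_a - f_bg, f_ab - f_b
    d_b, d_b_a = f_b - f_bg, f_ab - f_a
    if abs(eps) <= tolerance:
        klass = "none"
    else:
        flips = int(_sign_flips(d_a, d_a_b, tolerance)) \
            + int(_sign_flips(d_b, d_b_a, tolerance))
        klass = ("magnitude", "sign", "reciprocal_sign")[flips]
    return EpistasisResult(eps, d_a, d_a_b, d_b, d_b_a, klass, tolerance, query)


@dataclass
class ScanReport:
    """Results for satisfiable queries plus the missing genotypes of the rest."""

    results: list[EpistasisResult]
    unsatisfiable: list[tuple[EpistasisQuery, list[str]]]


def scan_epistasis(
    s: AnchorSet,
    queries: Iterable[EpistasisQuery],
    tolerance: float = 0.0,
    scale: str = "raw",
    agg: str = "geometric",
) -> ScanReport:
    """Evaluate ε for each query against the anchor set's fitness values.

    ``scale="raw"`` uses fold repression directly (the default, matching how
    ε is defined on measured fitness); ``scale="log2"`` takes log2 first,
    which on a planted additive+pairwise landscape recovers interaction
    terms exactly.  Replicate fitness values are combined by ``agg``.
    """
    if scale not in ("raw", "log2"):
        raise ValueError(f"unknown scale {scale!r}")
    fmap = s.fitness_map(agg=agg)
    if scale == "log2":
        fmap = {g: math.log2(f) for g, f in fmap.items()}
    results: list[EpistasisResult] = []
    unsat: list[tuple[EpistasisQuery, list[str]]] = []
    for q in queries:
        genos = q.genotypes()
        missing = [Variant(g, q.background.reference_id).label()
                   for g in genos if g not in fmap]
        if missing:
            unsat.append((q, missing))
            continue
        f_bg, f_a, f_b, f_ab = (fmap[g] for g in genos)
        results.append(classify_epistasis(f_bg, f_a, f_b, f_ab, tolerance, q))
    return ScanReport(results, unsat)


def enumerate_quadruples(s: AnchorSet, max_group_size: int = 1) -> list[EpistasisQuery]:
    """All (background, A, B) decompositions observable in the anchor set.

    A query is emitted iff all four genotypes g, g∪A, g∪B, g∪A∪B are present
    and |A|, |B| ≤ max_group_size; deduplicated under A↔B exchange by
    requiring A's sorted token tuple to precede B's.
    """
    if max_group_size < 1:
        raise ValueError("max_group_size must be >= 1")
    genotypes = s.genotypes()
    ref_id = s.reference_id
    out: list[EpistasisQuery] = []
    for top in genotypes:
        for bg in genotypes:
            if not bg < top:
                continue
            extra = top - bg
            if len(extra) < 2 or len(extra) > 2 * max_group_size:
                continue
            extra_sorted = sorted(extra, key=lambda m: (m.site, m.mut_aa))
            for size_a in range(1, len(extra)):
                if size_a > max_group_size or len(extra) - size_a > max_group_size:
                    continue
                for combo in combinations(extra_sorted, size_a):
                    a = frozenset(combo)
                    b = extra - a
                    key_a = tuple(str(m) for m in sorted(a, key=lambda m: (m.site, m.mut_aa)))
                    key_b = tuple(str(m) for m in sorted(b, key=lambda m: (m.site, m.mut_aa)))
                    if key_a > key_b:
                        continue  # A↔B symmetry: keep canonical order only
                    if (bg | a) in genotypes and (bg | b) in genotypes:
                        out.append(EpistasisQuery(Variant(bg, ref_id), a, b))
    out.sort(key=lambda q: q.label())
    return out
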