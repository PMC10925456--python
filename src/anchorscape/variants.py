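"""Genotype data model for substitution variants of a reference protein.

A :class:`Mutation` is a single amino-acid substitution written in the
field's usual ``S57R`` notation (wild-type letter, 1-based residue site,
mutant letter).  A :class:`Variant` is a site-consistent set of such
substitutions on one reference sequence; the empty set denotes wild type.
An :class:`AnchorSet` couples variants with measured fitness (fold
repression) and provenance, and is the central dataset of the pipeline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")

ANCHOR_SOURCES = ("supernatant", "plaque", "designed", "simulated")


@dataclass(frozen=True, order=True)
class Mutation:
    """A point substitution: wild-type residue, 1-based site, mutant residue."""

    site: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self) -> None:
        if self.site < 1:
            raise ValueError(f"site must be >= 1, got {self.site}")
        for aa, role in ((self.wt_aa, "wild-type"), (self.mut_aa, "mutant")):
            if aa not in AMINO_ACIDS:
                raise ValueError(f"{role} letter {aa!r} is not a standard amino acid")
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"synonymous token {self.wt_aa}{self.site}{self.mut_aa} rejected")

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.site}{self.mut_aa}"


def parse_mutation(token: str) -> Mutation:
    """Parse a ``S57R``-style substitution token.

    Raises ``ValueError`` on malformed tokens, non-amino-acid letters and
    synonymous (wt == mut) tokens.  ``str()`` of the result reproduces the
    token.
    """
    m = _MUTATION_RE.match(token.strip())
    if m is None:
        raise ValueError(f"malformed mutation token {token!r} (expected e.g. 'S57R')")
    wt, site, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    return Mutation(site=site, wt_aa=wt, mut_aa=mut)


@dataclass(frozen=True)
class Variant:
    """A set of substitutions on one reference; empty set is wild type."""

    mutations: frozenset[Mutation] = frozenset()
    reference_id: str = "ref"

    def __post_init__(self) -> None:
        sites = [m.site for m in self.mutations]
        if len(sites) != len(set(sites)):
            dup = sorted(s for s in set(sites) if sites.count(s) > 1)
            raise ValueError(f"multiple mutations at site(s) {dup}")

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)

    @property
    def is_wildtype(self) -> bool:
        return not self.mutations

    def sorted_mutations(self) -> list[Mutation]:
        return sorted(self.mutations, key=lambda m: (m.site, m.mut_aa))

    def label(self) -> str:
        """Canonical text form: ``WT`` or ``;``-joined tokens in site order."""
        if self.is_wildtype:
            return "WT"
        return ";".join(str(m) for m in self.sorted_mutations())

    def site_map(self) -> dict[int, str]:
        return {m.site: m.mut_aa for m in self.mutations}

    def validate_against(self, reference: str) -> None:
        """Check every wt letter and site against the reference sequence."""
        for m in self.sorted_mutations():
            if m.site > len(reference):
                raise ValueError(
                    f"mutation {m} beyond reference length {len(reference)}"
                )
            ref_aa = reference[m.site - 1]
            if ref_aa != m.wt_aa:
                raise ValueError(
                    f"mutation {m}: reference has {ref_aa} at site {m.site}, not {m.wt_aa}"
                )

    def __str__(self) -> str:
        return self.label()


def parse_variant(spec: str, reference: str, reference_id: str = "ref") -> Variant:
    """Parse ``"WT"`` or semicolon-separated tokens into a validated Variant.

    Order-insensitive; duplicates of the identical token collapse; two
    different mutations at one site, wt-letter mismatches and out-of-range
    sites raise ``ValueError``.
    """
    if not reference:
        raise ValueError("reference sequence must be nonempty")
    spec = spec.strip()
    if spec.upper() == "WT" or spec == "":
        return Variant(frozenset(), reference_id)
    muts = frozenset(parse_mutation(tok) for tok in spec.split(";") if tok.strip())
    v = Variant(muts, reference_id)
    v.validate_against(reference)
    return v


def apply_mutations(reference: str, v: Variant) -> str:
    """Apply a variant's substitutions to the reference sequence."""
    v.validate_against(reference)
    seq = list(reference)
    for m in v.mutations:
        seq[m.site - 1] = m.mut_aa
    return "".join(seq)


def variant_distance(a: Variant, b: Variant) -> int:
    """Number of residue positions at which the two mutated sequences differ.

    Symmetric, zero iff the genotypes are identical; for substitution-only
    variants this equals the Hamming distance between the applied sequences.
    """
    if a.reference_id != b.reference_id:
        raise ValueError(
            f"variants on different references: {a.reference_id!r} vs {b.reference_id!r}"
        )
    ma, mb = a.site_map(), b.site_map()
    d = 0
    for site in set(ma) | set(mb):
        if ma.get(site) != mb.get(site):
            d += 1
    return d


@dataclass(frozen=True)
class AnchorRecord:
    """A genotype with measured fitness (fold repression) and provenance."""

    variant: Variant
    fitness: float
    route_id: str = ""
    passage: int = 0
    source: str = "simulated"
    record_id: str = ""

    def __post_init__(self) -> None:
        if not self.fitness > 0:
            raise ValueError(f"fitness must be > 0, got {self.fitness}")
        if self.passage < 0:
            raise ValueError("passage must be nonnegative")
        if self.source not in ANCHOR_SOURCES:
            raise ValueError(f"unknown source {self.source!r}")


@dataclass
class AnchorSet:
    """A reference sequence plus an ordered collection of anchor records."""

    reference_sequence: str
    records: list[AnchorRecord] = field(default_factory=list)
    reference_id: str = "ref"

    def __post_init__(self) -> None:
        if not self.reference_sequence:
            raise ValueError("reference sequence must be nonempty")
        fixed = []
        seen_ids: set[str] = set()
        for i, rec in enumerate(self.records):
            rec.variant.validate_against(self.reference_sequence)
            rid = rec.record_id or f"r{i:03d}"
            if rid in seen_ids:
                raise ValueError(f"duplicate record id {rid!r}")
            seen_ids.add(rid)
            if rec.record_id != rid:
                rec = AnchorRecord(rec.variant, rec.fitness, rec.route_id,
                                   rec.passage, rec.source, rid)
            fixed.append(rec)
        self.records = fixed

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AnchorRecord]:
        return iter(self.records)

    def genotypes(self) -> set[frozenset[Mutation]]:
        return {rec.variant.mutations for rec in self.records}

    def fitness_map(self, agg: str = "geometric") -> dict[frozenset[Mutation], float]:
        """Fitness per distinct genotype; replicicates combined by ``agg``.

        Geometric mean is the default: fold changes are ratio-scaled.
        """
        import numpy as np

        groups: dict[frozenset[Mutation], list[float]] = {}
        for rec in self.records:
            groups.setdefault(rec.variant.mutations, []).append(rec.fitness)
        if agg == "geometric":
            return {g: v[0] if len(v) == 1 else float(np.exp(np.mean(np.log(v))))
                    for g, v in groups.items()}
        if agg == "arithmetic":
            return {g: v[0] if len(v) == 1 else float(np.mean(v))
                    for g, v in groups.items()}
        raise ValueError(f"unknown aggregation {agg!r}")


@dataclass(frozen=True)
class AnchorSummary:
    n_variants: int
    n_distinct_mutations: int
    n_distinct_sites: int
    fraction_gt2_mutations: float
    mutation_counts: dict[str, int] = field(default_factory=dict, compare=False)


def summarize_anchors(s: AnchorSet) -> AnchorSummary:
    """Tally distinct mutations/sites and the >2-mutation fraction.

    Duplicate genotypes (replicates) count once toward nothing here: each
    *record* counts toward ``n_variants`` and the fraction, while distinct
    mutation identities and sites are set unions over all records.
    """
    if len(s) == 0:
        raise ValueError("anchor set is empty")
    mutations: set[Mutation] = set()
    counts: dict[str, int] = {}
    n_gt2 = 0
    for rec in s:
        if rec.variant.n_mutations > 2:
            n_gt2 += 1
        for m in rec.variant.mutations:
            mutations.add(m)
            counts[str(m)] = counts.get(str(m), 0) + 1
    sites = {m.site for m in mutations}
    return AnchorSummary(
        n_variants=len(s),
        n_distinct_mutations=len(mutations),
        n_distinct_sites=len(sites),
        fraction_gt2_mutations=n_gt2 / len(s),
        mutation_counts=counts,
    )
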