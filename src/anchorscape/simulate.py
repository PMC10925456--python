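"""Synthetic landscapes and segmented-evolution simulation.

A :class:`GroundTruthLandscape` plants an additive + sparse-pairwise fitness
function (log2 fold-repression units) over a vocabulary of candidate
mutations grouped into contiguous gene segments.  Two evolution regimes are
simulated on top of it:

* :func:`simulate_segment_scan` — segment-restricted mutagenesis: a phage
  population is serially passaged across hosts, each host confining new
  mutations to one segment (the order given by a :class:`RouteSchedule`).
* :func:`simulate_pance` — the global-competition baseline: proposals may
  hit any candidate mutation and the whole population competes in one pool.

Both regimes share the same Wright–Fisher-like core: dilution bottleneck,
Poisson mutation proposals, multinomial selection-resampling proportional
to 2^(log2 fitness).  After each passage the dominant genotype and sampled
plaque genotypes are emitted as anchors with noisy observed fitness.

:func:`make_anchor_fixture` builds a deterministic 82-anchor benchmark set
(52 distinct mutations at 39 sites, 68/82 variants with >2 mutations) whose
fold-repression values come from a small planted landscape with interaction
terms chosen to exhibit negative, positive, magnitude, sign and
reciprocal-sign epistasis among named mutation groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .variants import (
    AMINO_ACIDS,
    AnchorRecord,
    AnchorSet,
    Mutation,
    Variant,
    parse_mutation,
)


# --------------------------------------------------------------------------
# planted landscapes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LandscapeConfig:
    """Structural parameters of a planted landscape.

    Defaults mirror the benchmark anchor-set scale: 8 usable segments,
    39 mutable sites carrying 52 candidate substitutions on a ~220-residue
    reference.  Effects are log2 fold-repression units.
    """

    n_segments: int = 8
    n_sites: int = 39
    n_candidates: int = 52
    reference_length: int = 220
    effect_mean: float = 0.5
    effect_sd: float = 0.3
    interaction_density: float = 0.05
    interaction_sd: float = 1.0
    sign_flip_prob: float = 0.3
    noise_sd: float = 0.1
    b0: float = math.log2(5.0)

    def __post_init__(self) -> None:
        if self.n_segments < 1 or self.n_sites < 1:
            raise ValueError("segments and sites must be >= 1")
        if not (self.n_sites <= self.n_candidates <= 19 * self.n_sites):
            raise ValueError("n_candidates must lie in [n_sites, 19*n_sites]")
        if self.n_sites > self.reference_length:
            raise ValueError("more sites than reference residues")
        if not 0.0 <= self.interaction_density <= 1.0:
            raise ValueError("interaction_density must be in [0, 1]")
        if not 0.0 <= self.sign_flip_prob <= 1.0:
            raise ValueError("sign_flip_prob must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class GroundTruthLandscape:
    """Additive + sparse pairwise-epistatic log2 fitness over candidates."""

    reference: str
    mutations: tuple[Mutation, ...]
    segments: tuple[tuple[int, ...], ...]  # candidate indices per segment
    additive: tuple[float, ...]
    interactions: dict[tuple[int, int], float]  # key (i, j) with i < j
    b0: float
    noise_sd: float
    seed: int
    reference_id: str = "ref"

    def __post_init__(self) -> None:
        sites = {}
        for idx, m in enumerate(self.mutations):
            sites[idx] = m.site
        for (i, j), e in self.interactions.items():
            if not (0 <= i < j < len(self.mutations)):
                raise ValueError(f"bad interaction key ({i}, {j})")
            if sites[i] == sites[j]:
                raise ValueError("interaction links two mutations at one site")
            if not math.isfinite(e):
                raise ValueError("interaction term must be finite")

    @property
    def n_candidates(self) -> int:
        return len(self.mutations)

    def index_of(self, m: Mutation) -> int:
        try:
            return self._index()[m]
        except KeyError:
            raise ValueError(f"mutation {m} is not a landscape candidate") from None

    def _index(self) -> dict[Mutation, int]:
        idx = getattr(self, "_idx_cache", None)
        if idx is None:
            idx = {m: i for i, m in enumerate(self.mutations)}
            object.__setattr__(self, "_idx_cache", idx)
        return idx

    def segment_of(self, candidate: int) -> int:
        for s, members in enumerate(self.segments):
            if candidate in members:
                return s
        raise ValueError(f"candidate {candidate} in no segment")

    def log2_fitness_indices(self, idxs: frozenset[int]) -> float:
        """b0 + additive terms + pairwise terms over candidate indices."""
        total = self.b0 + sum(self.additive[i] for i in idxs)
        for i, j in combinations(sorted(idxs), 2):
            total += self.interactions.get((i, j), 0.0)
        return total

    def variant_from_indices(self, idxs: Iterable[int]) -> Variant:
        return Variant(frozenset(self.mutations[i] for i in idxs), self.reference_id)


def true_fitness(landscape: GroundTruthLandscape, v: Variant) -> float:
    """Planted log2 fitness of a variant (b0 + additive + interactions)."""
    idxs = frozenset(landscape.index_of(m) for m in v.mutations)
    return landscape.log2_fitness_indices(idxs)


def _random_reference(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def make_landscape(config: LandscapeConfig, seed: int) -> GroundTruthLandscape:
    """Draw a planted landscape deterministically from a seed.

    Sites are sampled across the reference, sorted and chunked into
    contiguous segments (emulating gRNA windows); additive effects are
    Normal(effect_mean, effect_sd); interactions are planted on a Bernoulli
    (interaction_density) subset of site-distinct candidate pairs, and with
    probability sign_flip_prob an interaction overrides the singles' summed
    contribution so the pair is jointly beneficial regardless of the
    singles' signs — producing sign/reciprocal-sign epistasis, and fitness
    valleys wherever both singles are deleterious.
    """
    rng = np.random.default_rng(seed)
    reference = _random_reference(config.reference_length, rng)
    sites = sorted(rng.choice(np.arange(1, config.reference_length + 1),
                              size=config.n_sites, replace=False).tolist())
    # distribute candidates: every site gets one, extras get a second letter
    n_extra = config.n_candidates - config.n_sites
    extra_sites = set(rng.choice(np.array(sites), size=n_extra, replace=False).tolist()) \
        if n_extra else set()
    mutations: list[Mutation] = []
    for site in sites:
        wt = reference[site - 1]
        alts = [a for a in AMINO_ACIDS if a != wt]
        n_here = 2 if site in extra_sites else 1
        picks = rng.choice(alts, size=n_here, replace=False)
        for mut in picks:
            mutations.append(Mutation(site=site, wt_aa=wt, mut_aa=str(mut)))
    mutations.sort(key=lambda m: (m.site, m.mut_aa))

    # contiguous segments over the ordered sites
    site_chunks = np.array_split(np.array(sites), config.n_segments)
    segments = []
    for chunk in site_chunks:
        chunk_set = set(chunk.tolist())
        segments.append(tuple(i for i, m in enumerate(mutations) if m.site in chunk_set))

    additive = rng.normal(config.effect_mean, config.effect_sd, size=len(mutations))

    interactions: dict[tuple[int, int], float] = {}
    for i, j in combinations(range(len(mutations)), 2):
        if mutations[i].site == mutations[j].site:
            continue
        if rng.random() < config.interaction_density:
            if rng.random() < config.sign_flip_prob:
                e = -(additive[i] + additive[j]) + abs(rng.normal(0.0, config.interaction_sd))
            else:
                e = rng.normal(0.0, config.interaction_sd)
            interactions[(i, j)] = float(e)

    return GroundTruthLandscape(
        reference=reference,
        mutations=tuple(mutations),
        segments=tuple(segments),
        additive=tuple(float(a) for a in additive),
        interactions=interactions,
        b0=config.b0,
        noise_sd=config.noise_sd,
        seed=int(seed),
    )


# --------------------------------------------------------------------------
# evolution simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RouteSchedule:
    """One evolutionary route: the ordered hosts (segments) a phage visits."""

    segment_order: tuple[int, ...]
    passages_per_segment: int = 1
    dilution: int = 50
    population_size: int = 1000
    plaques_per_passage: int = 2
    route_id: str = "route"

    def __post_init__(self) -> None:
        if self.passages_per_segment < 1 or self.dilution < 1:
            raise ValueError("passage and dilution counts must be >= 1")
        if self.population_size < 2 or self.plaques_per_passage < 0:
            raise ValueError("bad population/plaque configuration")


@dataclass
class SimulatedAnchorSet:
    """An anchor set plus the ground truth that generated it."""

    anchor_set: AnchorSet
    true_log2: dict[str, float]  # record id -> planted log2 fitness
    landscape: GroundTruthLandscape

    def distinct_mutated_sites(self) -> set[int]:
        return {m.site for rec in self.anchor_set for m in rec.variant.mutations}

    def distinct_mutations(self) -> set[Mutation]:
        return {m for rec in self.anchor_set for m in rec.variant.mutations}


def _mutate_individuals(
    genotypes: list[frozenset[int]],
    allowed: Sequence[int],
    landscape: GroundTruthLandscape,
    rate: float,
    rng: np.random.Generator,
) -> list[frozenset[int]]:
    """Apply Poisson(rate) segment-restricted proposals to each individual.

    Proposals landing on an already-mutated site are discarded (substitution
    model only; no reversions)."""
    if not allowed or rate <= 0:
        return genotypes
    out = []
    allowed_arr = np.asarray(allowed)
    n_props = rng.poisson(rate, size=len(genotypes))
    for geno, k in zip(genotypes, n_props):
        if k == 0:
            out.append(geno)
            continue
        current = set(geno)
        occupied = {landscape.mutations[i].site for i in current}
        for cand in rng.choice(allowed_arr, size=int(k)):
            site = landscape.mutations[int(cand)].site
            if site not in occupied:
                current.add(int(cand))
                occupied.add(site)
        out.append(frozenset(current))
    return out


def _passage(
    population: dict[frozenset[int], int],
    allowed: Sequence[int],
    landscape: GroundTruthLandscape,
    rng: np.random.Generator,
    population_size: int,
    dilution: int,
    proposal_rate: float,
    selection_strength: float,
    selection_saturation: float | None,
) -> dict[frozenset[int], int]:
    """One bottleneck → mutate → select-regrow cycle.

    ``selection_saturation`` caps the log2 fitness *seen by selection* at
    b0 + saturation: the transcriptional coupling between repressor
    function and phage propagation saturates, so selection cannot tell
    apart variants above the ceiling (true fitness is unaffected)."""
    genos = list(population)
    counts = np.array([population[g] for g in genos], dtype=float)
    # dilution bottleneck
    n_b = max(2, population_size // dilution)
    picks = rng.multinomial(n_b, counts / counts.sum())
    survivors: list[frozenset[int]] = []
    for g, c in zip(genos, picks):
        survivors.extend([g] * int(c))
    # segment-restricted (or global) mutagenesis on the surviving lineages
    survivors = _mutate_individuals(survivors, allowed, landscape,
                                    proposal_rate, rng)
    # fitness-proportional regrowth to fixed population size
    uniq: dict[frozenset[int], int] = {}
    for g in survivors:
        uniq[g] = uniq.get(g, 0) + 1
    ug = list(uniq)
    cap = (landscape.b0 + selection_saturation
           if selection_saturation is not None else None)
    lf = [landscape.log2_fitness_indices(g) for g in ug]
    if cap is not None:
        lf = [min(x, cap) for x in lf]
    w = np.array([uniq[g] * 2.0 ** (selection_strength * x)
                  for g, x in zip(ug, lf)])
    new_counts = rng.multinomial(population_size, w / w.sum())
    return {g: int(c) for g, c in zip(ug, new_counts) if c > 0}


def _geno_label(landscape: GroundTruthLandscape, g: frozenset[int]) -> str:
    return landscape.variant_from_indices(g).label()


def _emit_records(
    population: dict[frozenset[int], int],
    landscape: GroundTruthLandscape,
    rng: np.random.Generator,
    route_id: str,
    passage: int,
    plaques: int,
    records: list[AnchorRecord],
    true_log2: dict[str, float],
) -> None:
    """Emit the dominant genotype plus sampled plaque genotypes as anchors."""

    def add(geno: frozenset[int], source: str) -> None:
        rid = f"{route_id}.p{passage}.{source[:2]}{len(records)}"
        lf = landscape.log2_fitness_indices(geno)
        observed = 2.0 ** (lf + rng.normal(0.0, landscape.noise_sd))
        records.append(AnchorRecord(
            variant=landscape.variant_from_indices(geno),
            fitness=observed, route_id=route_id, passage=passage,
            source=source, record_id=rid))
        true_log2[rid] = lf

    genos = list(population)
    dominant = max(genos, key=lambda g: (population[g], _geno_label(landscape, g)))
    add(dominant, "supernatant")
    counts = np.array([population[g] for g in genos], dtype=float)
    if plaques > 0:
        # each plaque is one random phage individual; repeated picks of the
        # same genotype collapse to one record
        idx = rng.choice(len(genos), size=plaques, replace=True,
                         p=counts / counts.sum())
        for i in sorted(set(idx.tolist())):
            add(genos[i], "plaque")


def simulate_segment_scan(
    landscape: GroundTruthLandscape,
    routes: Iterable[RouteSchedule],
    seed: int,
    proposal_rate: float = 0.15,
    selection_strength: float = 4.0,
    selection_saturation: float | None = 3.0,
) -> SimulatedAnchorSet:
    """Serial passaging of a wild-type population across segment-hosts.

    Each route starts from wild type; at every passage, proposals are
    confined to the route's currently active segment.  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(seed)
    records: list[AnchorRecord] = []
    true_log2: dict[str, float] = {}
    wt: frozenset[int] = frozenset()
    # the scan always reports the starting wild type once
    rid = "wt.p0.su0"
    records.append(AnchorRecord(
        variant=landscape.variant_from_indices(wt),
        fitness=2.0 ** (landscape.b0 + rng.normal(0.0, landscape.noise_sd)),
        route_id="wt", passage=0, source="supernatant", record_id=rid))
    true_log2[rid] = landscape.b0

    n_segments = len(landscape.segments)
    for route in routes:
        for s in route.segment_order:
            if not 0 <= s < n_segments:
                raise ValueError(f"route {route.route_id!r}: unknown segment {s}")
        population: dict[frozenset[int], int] = {wt: route.population_size}
        passage = 0
        for seg in route.segment_order:
            allowed = landscape.segments[seg]
            for _ in range(route.passages_per_segment):
                passage += 1
                population = _passage(
                    population, allowed, landscape, rng,
                    route.population_size, route.dilution,
                    proposal_rate, selection_strength,
                    selection_saturation)
                _emit_records(population, landscape, rng, route.route_id,
                              passage, route.plaques_per_passage,
                              records, true_log2)
    anchors = AnchorSet(landscape.reference, records, landscape.reference_id)
    return SimulatedAnchorSet(anchors, true_log2, landscape)


def simulate_pance(
    landscape: GroundTruthLandscape,
    passages: int,
    seed: int,
    population_size: int = 1000,
    dilution: int = 50,
    proposal_rate: float = 0.15,
    plaques_per_passage: int = 2,
    selection_strength: float = 4.0,
    selection_saturation: float | None = 3.0,
) -> SimulatedAnchorSet:
    """Global-competition baseline: untargeted proposals, one pool.

    Identical passage dynamics to the segmented scan, but proposals may hit
    any candidate mutation and there is a single population throughout.
    ``passages=0`` returns only the wild-type record.
    """
    if passages < 0:
        raise ValueError("passages must be nonnegative")
    rng = np.random.default_rng(seed)
    records: list[AnchorRecord] = []
    true_log2: dict[str, float] = {}
    wt: frozenset[int] = frozenset()
    rid = "pance.p0.su0"
    records.append(AnchorRecord(
        variant=landscape.variant_from_indices(wt),
        fitness=2.0 ** (landscape.b0 + rng.normal(0.0, landscape.noise_sd)),
        route_id="pance", passage=0, source="supernatant", record_id=rid))
    true_log2[rid] = landscape.b0

    allowed = tuple(range(landscape.n_candidates))
    population: dict[frozenset[int], int] = {wt: population_size}
    for passage in range(1, passages + 1):
        population = _passage(population, allowed, landscape, rng,
                              population_size, dilution, proposal_rate,
                              selection_strength, selection_saturation)
        _emit_records(population, landscape, rng, "pance", passage,
                      plaques_per_passage, records, true_log2)
    anchors = AnchorSet(landscape.reference, records, landscape.reference_id)
    return SimulatedAnchorSet(anchors, true_log2, landscape)


# --------------------------------------------------------------------------
# cytometry event sampling
# --------------------------------------------------------------------------

def sample_flow_events(true_median: float, cv: float, n: int, seed: int) -> np.ndarray:
    """Lognormal event draws with the requested median and CV.

    For LogNormal(mu, sigma): median = exp(mu) and CV^2 = exp(sigma^2) - 1,
    so mu = ln(median), sigma = sqrt(ln(1 + CV^2)).
    """
    if true_median <= 0 or cv <= 0 or n < 1:
        raise ValueError("need true_median > 0, cv > 0, n >= 1")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=math.log(true_median), sigma=sigma, size=n)


# --------------------------------------------------------------------------
# the deterministic 82-anchor benchmark fixture
# --------------------------------------------------------------------------

_FIXTURE_SEED = 20240517
_FIXTURE_REF_LEN = 220

# wild-type letters implied by the named mutation labels
_NAMED_MUTATIONS = (
    "D33E", "R43S", "S57R", "A75T", "I80V", "G83V",
    "C93R", "P94L", "D119N", "V188F", "A199S", "G212S",
)

# planted additive log2 effects for named mutations (fold-repression units)
_NAMED_EFFECTS = {
    "D33E": 1.0, "R43S": 0.6, "S57R": 1.5, "A75T": 0.4, "I80V": 0.45,
    "G83V": 0.4, "C93R": 0.35, "P94L": 0.5, "D119N": 0.5, "V188F": 0.9,
    "A199S": 0.4, "G212S": 0.4,
}

# planted pairwise interactions (log2) chosen so that, on the raw
# fold-repression scale: D33E x S57R is negative; [S57R P94L] x V188F is
# positive; P94L x [G83V V188F A199S G212S] is reciprocal-sign and
# D33E x [P94L V188F] is magnitude, both in the S57R background.
_NAMED_INTERACTIONS = {
    ("D33E", "S57R"): -0.8,
    ("S57R", "P94L"): -1.0,
    ("S57R", "V188F"): -2.2,
    ("P94L", "V188F"): 2.5,
    ("D33E", "P94L"): 0.4,
}

_FIXTURE_B0 = math.log2(5.0)  # wild-type fold repression of 5

# hand-built genotypes: the epistasis demonstration set (17 variants)
_DEMO_VARIANTS = (
    "S57R", "D33E", "P94L", "R43S", "V188F",
    "D33E;S57R", "S57R;P94L", "S57R;V188F", "S57R;I80V",
    "S57R;P94L;V188F", "S57R;I80V;P94L",
    "S57R;G83V;V188F;A199S;G212S",
    "S57R;P94L;G83V;V188F;A199S;G212S",
    "D33E;S57R;A75T;C93R",
    "R43S;D33E;S57R;A75T;C93R",
    "D33E;S57R;P94L;V188F",
    "D33E;S57R;D119N",
)


def fixture_mutation_effects() -> tuple[dict[str, float], dict[frozenset[str], float], float]:
    """The fixture's planted additive effects, interactions and baseline."""
    rng = np.random.default_rng(_FIXTURE_SEED + 1)
    effects = dict(_NAMED_EFFECTS)
    for tok in _fixture_mutation_tokens():
        if tok not in effects:
            effects[tok] = float(rng.uniform(0.15, 0.9))
    inter = {frozenset(k): v for k, v in _NAMED_INTERACTIONS.items()}
    return effects, inter, _FIXTURE_B0


def _fixture_reference() -> str:
    rng = np.random.default_rng(_FIXTURE_SEED)
    seq = list(_random_reference(_FIXTURE_REF_LEN, rng))
    for tok in _NAMED_MUTATIONS:
        m = parse_mutation(tok)
        seq[m.site - 1] = m.wt_aa
    return "".join(seq)


def _fixture_mutation_tokens() -> list[str]:
    """The fixture's 52 mutation tokens: 12 named + 40 generated.

    39 distinct sites: the 12 named plus 27 generated; 13 generated sites
    carry two alternative substitutions (39 + 13 = 52 mutations)."""
    reference = _fixture_reference()
    named = [parse_mutation(t) for t in _NAMED_MUTATIONS]
    named_sites = {m.site for m in named}
    rng = np.random.default_rng(_FIXTURE_SEED + 2)
    pool = [s for s in range(2, _FIXTURE_REF_LEN) if s not in named_sites]
    extra_sites = sorted(rng.choice(np.array(pool), size=27, replace=False).tolist())
    tokens = list(_NAMED_MUTATIONS)
    for rank, site in enumerate(extra_sites):
        wt = reference[site - 1]
        alts = [a for a in AMINO_ACIDS if a != wt]
        n_here = 2 if rank < 13 else 1
        for mut in rng.choice(alts, size=n_here, replace=False):
            tokens.append(f"{wt}{site}{mut}")
    return tokens


def _fixture_fitness(muts: frozenset[Mutation],
                     effects: dict[str, float],
                     inter: dict[frozenset[str], float]) -> float:
    log2f = _FIXTURE_B0 + sum(effects[str(m)] for m in muts)
    for a, b in combinations(sorted(muts, key=str), 2):
        log2f += inter.get(frozenset({str(a), str(b)}), 0.0)
    return 2.0 ** log2f


def make_anchor_fixture() -> AnchorSet:
    """Deterministic 82-anchor benchmark set.

    Exactly 82 distinct genotypes over 52 distinct mutations at 39 sites,
    68/82 (~83%) with more than 2 mutations.  Fold-repression values come
    from the planted fixture landscape; every regeneration is identical.
    """
    reference = _fixture_reference()
    tokens = _fixture_mutation_tokens()
    mut_by_token = {t: parse_mutation(t) for t in tokens}
    effects, inter, _ = fixture_mutation_effects()
    rng = np.random.default_rng(_FIXTURE_SEED + 3)

    genotypes: list[frozenset[Mutation]] = []
    seen: set[frozenset[Mutation]] = set()

    def push(muts: frozenset[Mutation]) -> bool:
        if muts in seen:
            return False
        sites = [m.site for m in muts]
        if len(sites) != len(set(sites)):
            return False
        seen.add(muts)
        genotypes.append(muts)
        return True

    for spec in _DEMO_VARIANTS:
        ok = push(frozenset(mut_by_token[t] for t in spec.split(";")))
        assert ok, f"demo variant {spec} duplicated"

    # five filler doubles from generated mutations (distinct sites)
    generated = [t for t in tokens if t not in _NAMED_MUTATIONS]
    filler_pairs = 0
    i = 0
    while filler_pairs < 5:
        a, b = mut_by_token[generated[i]], mut_by_token[generated[i + 1]]
        if a.site != b.site and push(frozenset({a, b})):
            filler_pairs += 1
        i += 2

    # sixty random >2-mutation variants, covering every unused mutation
    used = {str(m) for g in genotypes for m in g}
    unused = [t for t in tokens if t not in used]
    sizes = [3, 4, 3, 5, 3, 4, 6, 3, 4, 5]
    k = 0
    while len(genotypes) < 82:
        size = sizes[k % len(sizes)]
        k += 1
        picked: list[Mutation] = []
        sites: set[int] = set()
        # coverage first: take up to size-1 not-yet-used mutations
        while unused and len(picked) < size - 1:
            cand = mut_by_token[unused[0]]
            if cand.site in sites:
                break
            picked.append(cand)
            sites.add(cand.site)
            unused.pop(0)
        guard = 0
        while len(picked) < size:
            guard += 1
            if guard > 200:
                break
            cand = mut_by_token[tokens[int(rng.integers(len(tokens)))]]
            if cand.site not in sites:
                picked.append(cand)
                sites.add(cand.site)
        if len(picked) >= 3:
            push(frozenset(picked))

    records = []
    for n, muts in enumerate(genotypes):
        records.append(AnchorRecord(
            variant=Variant(muts, "ref"),
            fitness=_fixture_fitness(muts, effects, inter),
            route_id=f"R{n % 8 + 1}", passage=n % 8 + 1,
            source="plaque", record_id=f"a{n:03d}"))
    return AnchorSet(reference, records, "ref")


def fixture_with_wildtype() -> AnchorSet:
    """The 82-anchor fixture plus a wild-type record (fold repression 5).

    Wild type is measured alongside the anchors but is not itself an
    anchor; epistasis queries in the wild-type background need its fitness.
    """
    base = make_anchor_fixture()
    wt = AnchorRecord(variant=Variant(frozenset(), "ref"),
                      fitness=2.0 ** _FIXTURE_B0, route_id="wt",
                      passage=0, source="plaque", record_id="wt")
    return AnchorSet(base.reference_sequence, [wt, *base.records], "ref")


def sample_anchor_set(
    landscape: GroundTruthLandscape,
    n: int,
    seed: int,
    min_mutations: int = 1,
    max_mutations: int = 6,
    noisy: bool = False,
) -> SimulatedAnchorSet:
    """Draw n distinct random genotypes from a landscape as an anchor set.

    Genotype sizes are uniform on [min_mutations, max_mutations]; sites are
    kept distinct within a genotype.  Observed fitness is exactly
    2^(planted log2 fitness) unless ``noisy``, which adds Gaussian log2
    noise of the landscape's noise_sd.
    """
    if n < 1 or min_mutations < 0 or max_mutations < min_mutations:
        raise ValueError("bad sampling configuration")
    rng = np.random.default_rng(seed)
    seen: set[frozenset[int]] = set()
    records: list[AnchorRecord] = []
    true_log2: dict[str, float] = {}
    guard = 0
    while len(records) < n:
        guard += 1
        if guard > 200 * n:
            raise RuntimeError("could not draw enough distinct genotypes")
        size = int(rng.integers(min_mutations, max_mutations + 1))
        picked: set[int] = set()
        sites: set[int] = set()
        for cand in rng.permutation(landscape.n_candidates):
            if len(picked) == size:
                break
            site = landscape.mutations[int(cand)].site
            if site not in sites:
                picked.add(int(cand))
                sites.add(site)
        geno = frozenset(picked)
        if geno in seen or len(geno) != size:
            continue
        seen.add(geno)
        rid = f"s{len(records):03d}"
        lf = landscape.log2_fitness_indices(geno)
        noise = rng.normal(0.0, landscape.noise_sd) if noisy else 0.0
        records.append(AnchorRecord(
            variant=landscape.variant_from_indices(geno),
            fitness=2.0 ** (lf + noise), route_id="sample", passage=0,
            source="simulated", record_id=rid))
        true_log2[rid] = lf
    anchors = AnchorSet(landscape.reference, records, landscape.reference_id)
    return SimulatedAnchorSet(anchors, true_log2, landscape)


def default_routes(n_routes: int = 8, n_segments: int = 8,
                   population_size: int = 500) -> list[RouteSchedule]:
    """Rotated route schedules: route r visits segments r, r+1, ... mod S."""
    return [RouteSchedule(
        segment_order=tuple((r + i) % n_segments for i in range(n_segments)),
        route_id=f"R{r + 1}", population_size=population_size)
        for r in range(n_routes)]


def site_discovery_contrast(
    landscape: GroundTruthLandscape,
    seed: int,
    proposal_rate: float = 0.15,
) -> tuple[int, int]:
    """Distinct mutated sites discovered: segmented routes vs one big pool.

    The two arms are matched resource-for-resource: eight parallel routes of
    500 phage passaged eight times each, against a single globally-competing
    pool of 4000 phage passaged eight times with sixteen plaque picks per
    passage — equal total population, passages, mutation proposals and
    plaque observations; the only difference is segment restriction and
    parallelization.  Returns (segmented_sites, global_sites).
    """
    n_seg = len(landscape.segments)
    routes = default_routes(n_routes=n_seg, n_segments=n_seg)
    ev = simulate_segment_scan(landscape, routes, seed=seed,
                          proposal_rate=proposal_rate)
    pa = simulate_pance(landscape, passages=n_seg, seed=seed,
                        population_size=500 * n_seg,
                        proposal_rate=proposal_rate,
                        plaques_per_passage=2 * n_seg)
    return (len(ev.distinct_mutated_sites()), len(pa.distinct_mutated_sites()))
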