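"""Genome map, meiosis and breeding-population simulation.

The simulated species is a diploid with ``group_count`` linkage groups of
equally spaced biallelic markers (alleles coded 0/1).  Two fully divergent
inbred founders are crossed to give an F₁, whose selfed progeny form the F₂
base population.  From the F₂, populations are advanced by self-pollination
(S₁..S₄), random mating (A₁..A₄) or recurrent backcrossing (Bc₁..Bc₄).

Meiosis uses the Haldane mapping function (independent crossovers, no
interference): the recombination fraction between adjacent markers ``d`` cM
apart is ``(1 - exp(-2 d / 100)) / 2`` and linkage groups assort freely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidConfigurationError

__all__ = [
    "GeneticMap",
    "Population",
    "build_map",
    "recombination_fraction",
    "make_founders",
    "make_gamete",
    "make_f2",
    "f1_genotype",
    "advance",
    "advance_series",
]

SYSTEMS = ("selfing", "random_mating", "backcross")
SYSTEM_PREFIX = {"selfing": "S", "random_mating": "A", "backcross": "Bc"}


@dataclass(frozen=True)
class GeneticMap:
    """Marker map: ``group_count`` linkage groups of equally spaced markers."""

    group_count: int
    markers_per_group: int
    spacing: float  # cM between adjacent markers
    marker_ids: tuple[str, ...] = field(repr=False)
    group_of_marker: np.ndarray = field(repr=False)  # (n_markers,) int
    positions: np.ndarray = field(repr=False)  # within-group position, cM

    @property
    def n_markers(self) -> int:
        return self.group_count * self.markers_per_group

    @property
    def total_length(self) -> float:
        """Total map length in cM (sum of within-group spans)."""
        return self.group_count * (self.markers_per_group - 1) * self.spacing

    def group_slice(self, group: int) -> slice:
        m = self.markers_per_group
        return slice(group * m, (group + 1) * m)

    def switch_probabilities(self) -> np.ndarray:
        """Per-marker probability that a gamete switches source haplotype
        just before this marker.  Group starts get 1/2 (free recombination
        between groups and a uniform start for the first group)."""
        c = recombination_fraction(self.spacing)
        prob = np.full(self.n_markers, c)
        prob[:: self.markers_per_group] = 0.5
        return prob


def build_map(group_count: int = 10, markers_per_group: int = 101,
              spacing: float = 1.0) -> GeneticMap:
    """Build an evenly saturated genetic map.

    Defaults give the reference genome used throughout: 10 linkage groups
    of 101 markers at 1 cM spacing, i.e. 1,010 markers over 1,000 cM.
    """
    if group_count < 1 or markers_per_group < 1:
        raise InvalidConfigurationError(
            "group_count and markers_per_group must be positive integers")
    if spacing <= 0:
        raise InvalidConfigurationError("spacing must be a positive distance in cM")
    n = group_count * markers_per_group
    groups = np.repeat(np.arange(group_count), markers_per_group)
    offsets = np.tile(np.arange(markers_per_group), group_count)
    positions = offsets * float(spacing)
    ids = tuple(f"G{g + 1}_M{o + 1}" for g, o in zip(groups, offsets))
    return GeneticMap(group_count, markers_per_group, float(spacing),
                      ids, groups, positions)


def recombination_fraction(distance_cM: float) -> float:
    """Haldane map function: c = (1 - exp(-2 d / 100)) / 2, for d in cM."""
    d = np.asarray(distance_cM, dtype=float)
    if np.any(d < 0):
        raise InvalidConfigurationError("map distance must be non-negative")
    return float((1.0 - np.exp(-2.0 * d / 100.0)) / 2.0) if d.ndim == 0 \
        else (1.0 - np.exp(-2.0 * d / 100.0)) / 2.0


@dataclass
class Population:
    """Phased diploid genotypes for a cohort of individuals.

    ``haplotypes`` has shape (n, 2, n_markers) with alleles coded 0/1.
    Haplotype order within an individual carries no meaning.
    """

    haplotypes: np.ndarray
    generation_label: str
    system: str  # one of SYSTEMS or "base"
    map: GeneticMap

    def __post_init__(self):
        h = np.asarray(self.haplotypes, dtype=np.int8)
        if h.ndim != 3 or h.shape[1] != 2 or h.shape[2] != self.map.n_markers:
            raise InvalidConfigurationError(
                "haplotypes must have shape (n, 2, n_markers) aligned to the map")
        self.haplotypes = h

    @property
    def size(self) -> int:
        return self.haplotypes.shape[0]

    def dosages(self) -> np.ndarray:
        """Genotype dosage matrix (n x markers), values 0/1/2."""
        return self.haplotypes.sum(axis=1, dtype=np.int8)

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=(0, 1))

    def heterozygosity(self) -> float:
        """Mean observed heterozygosity across individuals and loci."""
        return float((self.haplotypes[:, 0, :] != self.haplotypes[:, 1, :]).mean())

    def gametes(self) -> np.ndarray:
        """The 2n observed haplotypes as a (2n x markers) array."""
        return self.haplotypes.reshape(-1, self.map.n_markers)


def make_founders(gmap: GeneticMap) -> tuple[np.ndarray, np.ndarray]:
    """Two maximally divergent inbred founders.

    Returns two (2, n_markers) haplotype pairs: parent 1 is homozygous for
    allele 1 at every locus, parent 2 for allele 0.
    """
    m = gmap.n_markers
    p1 = np.ones((2, m), dtype=np.int8)
    p2 = np.zeros((2, m), dtype=np.int8)
    return p1, p2


def f1_genotype(gmap: GeneticMap) -> np.ndarray:
    """The F₁ of the divergent founders: heterozygous at every locus with
    known phase (one all-1 and one all-0 haplotype)."""
    p1, p2 = make_founders(gmap)
    return np.stack([p1[0], p2[0]])


def _gametes_from(haplotypes: np.ndarray, parent_idx: np.ndarray,
                  gmap: GeneticMap, rng: np.random.Generator,
                  linked: bool = True) -> np.ndarray:
    """One recombinant gamete from each listed parent (vectorised meiosis).

    ``linked=False`` transmits every locus independently (free
    recombination between all markers), ignoring the map distances.
    """
    k = parent_idx.shape[0]
    m = gmap.n_markers
    prob = gmap.switch_probabilities() if linked else 0.5
    switch = rng.random((k, m)) < prob
    # cumulative XOR of switch events selects the source haplotype per marker
    source = np.cumsum(switch, axis=1) & 1
    parents = haplotypes[parent_idx]  # (k, 2, m)
    return parents[np.arange(k)[:, None], source, np.arange(m)]


def make_gamete(individual: np.ndarray, gmap: GeneticMap,
                rng: np.random.Generator) -> np.ndarray:
    """A single recombinant gamete from one individual's (2, m) haplotypes."""
    haps = np.asarray(individual, dtype=np.int8)[None, :, :]
    return _gametes_from(haps, np.zeros(1, dtype=int), gmap, rng)[0]


def make_f2(parent1: np.ndarray, parent2: np.ndarray, n: int,
            gmap: GeneticMap, rng: np.random.Generator) -> Population:
    """F₂ base population: each individual unites two independent F₁ gametes."""
    if n < 2:
        raise InvalidConfigurationError("F2 size must be at least 2")
    for p in (parent1, parent2):
        h = np.asarray(p)
        if np.any(h[0] != h[1]):
            raise InvalidConfigurationError("founders must be fully homozygous")
    if not np.all(np.asarray(parent1)[0] != np.asarray(parent2)[0]):
        raise InvalidConfigurationError("founders must be divergent at every locus")
    f1 = np.stack([np.asarray(parent1, dtype=np.int8)[0],
                   np.asarray(parent2, dtype=np.int8)[0]])[None, :, :]
    idx = np.zeros(n, dtype=int)
    g1 = _gametes_from(f1, idx, gmap, rng)
    g2 = _gametes_from(f1, idx, gmap, rng)
    haps = np.stack([g1, g2], axis=1)
    return Population(haps, "F2", "base", gmap)


def _next_label(pop: Population, system: str) -> str:
    prefix = SYSTEM_PREFIX[system]
    label = pop.generation_label
    if label.startswith(prefix) and label[len(prefix):].isdigit():
        return f"{prefix}{int(label[len(prefix):]) + 1}"
    return f"{prefix}1"


MODES = ("meiosis", "independent_loci", "allele_resampling")


def advance(pop: Population, system: str, rng: np.random.Generator,
            mode: str = "meiosis",
            recurrent: np.ndarray | Population | None = None) -> Population:
    """Advance a population one generation; size is preserved.

    Mating systems
        selfing
            Each individual contributes exactly one selfed offspring (two
            independent gametes from itself), so heterozygosity halves per
            generation in expectation.
        random_mating
            Each offspring unites gametes from two distinct parents drawn
            uniformly with replacement.
        backcross
            Each offspring unites one gamete from a random individual of
            the current population with one gamete from the recurrent
            parent — the all-heterozygous F₁ genotype by default; a
            Population (e.g. the F₂ itself, sampling a random recurrent
            individual per offspring) or an inbred founder may be passed.

    Transmission modes
        meiosis
            Linked transmission: crossovers between adjacent markers at
            the Haldane recombination fraction of their map distance, free
            recombination between linkage groups.
        independent_loci
            Every locus is transmitted independently (free recombination
            between all markers): single-locus genotype dynamics follow
            the mating system but gametic disequilibrium halves each
            generation instead of persisting through linkage.
        allele_resampling (random_mating only)
            Offspring haplotypes are drawn locus-by-locus from
            Bernoulli(current allele frequency): allele frequencies are
            preserved in expectation but all linkage disequilibrium — and
            all family structure — is destroyed in a single generation.
    """
    if system not in SYSTEMS:
        raise InvalidConfigurationError(f"unknown mating system: {system!r}")
    if mode not in MODES:
        raise InvalidConfigurationError(f"unknown advancement mode: {mode!r}")
    if mode == "allele_resampling" and system != "random_mating":
        raise InvalidConfigurationError(
            "allele_resampling is defined only for random_mating")
    n = pop.size
    if n == 0:
        raise InvalidConfigurationError("cannot advance an empty population")
    gmap = pop.map
    label = _next_label(pop, system)
    linked = mode == "meiosis"

    if system == "selfing":
        idx = np.arange(n)
        g1 = _gametes_from(pop.haplotypes, idx, gmap, rng, linked)
        g2 = _gametes_from(pop.haplotypes, idx, gmap, rng, linked)
    elif system == "random_mating" and mode == "allele_resampling":
        p = pop.allele_frequencies()
        haps = (rng.random((n, 2, gmap.n_markers)) < p).astype(np.int8)
        return Population(haps, label, system, gmap)
    elif system == "random_mating":
        if n < 2:
            raise InvalidConfigurationError(
                "random mating without selfing needs at least 2 individuals")
        mothers = rng.integers(n, size=n)
        fathers = rng.integers(n, size=n)
        clash = fathers == mothers
        while np.any(clash):  # exclude self-fertilisation
            fathers[clash] = rng.integers(n, size=int(clash.sum()))
            clash = fathers == mothers
        g1 = _gametes_from(pop.haplotypes, mothers, gmap, rng, linked)
        g2 = _gametes_from(pop.haplotypes, fathers, gmap, rng, linked)
    else:  # backcross
        parents = rng.integers(n, size=n)
        g1 = _gametes_from(pop.haplotypes, parents, gmap, rng, linked)
        if isinstance(recurrent, Population):
            ridx = rng.integers(recurrent.size, size=n)
            g2 = _gametes_from(recurrent.haplotypes, ridx, gmap, rng, linked)
        else:
            rec = f1_genotype(gmap) if recurrent is None else \
                np.asarray(recurrent, dtype=np.int8)
            g2 = _gametes_from(rec[None, :, :], np.zeros(n, dtype=int),
                               gmap, rng, linked)

    return Population(np.stack([g1, g2], axis=1), label, system, gmap)


def advance_series(base: Population, system: str, generations: int,
                   rng: np.random.Generator, mode: str = "meiosis",
                   recurrent: np.ndarray | Population | None = None
                   ) -> list[Population]:
    """Advance ``generations`` times from ``base``; returns the new cohorts
    in order (the base population is not included)."""
    out: list[Population] = []
    pop = base
    for _ in range(generations):
        pop = advance(pop, system, rng, mode=mode, recurrent=recurrent)
        out.append(pop)
    return out
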