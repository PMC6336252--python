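"""Quantitative-trait simulation on the simulated genome.

A trait is controlled by 20 QTL (two per linkage group).  Locus ``j``
contributes additively ``a_j = p_j * a`` with the genotype scored +1 / 0 / -1
for the favourable homozygote / heterozygote / other homozygote, plus a
dominance deviation ``d_j = (d/a) * a_j`` for heterozygotes.  The locus
weights ``p_j`` are the symmetric binomial probabilities C(19, j-1) / 2^19,
so a few central loci dominate the trait.  Phenotypes are
``P_i = G_i + E_i`` with ``E_i ~ N(0, sigma2_e)`` and the environmental
variance chosen so that the broad-sense heritability in the base population
hits its target: ``sigma2_e = sigma2_g (1 - h2) / h2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .errors import InvalidConfigurationError
from .popsim import GeneticMap, Population

__all__ = [
    "TraitArchitecture",
    "PhenotypeSet",
    "binomial_weights",
    "assign_qtl",
    "genetic_value",
    "genetic_variance_f2",
    "environmental_variance",
    "simulate_phenotypes",
]


def binomial_weights(s: int) -> np.ndarray:
    """Weights C(s, k) / 2^s for k = 0..s; symmetric and summing to 1."""
    if s < 0:
        raise InvalidConfigurationError("s must be non-negative")
    return binom.pmf(np.arange(s + 1), s, 0.5)


def assign_qtl(gmap: GeneticMap, fractions: tuple[float, float] = (0.25, 0.75),
               rng: np.random.Generator | None = None) -> np.ndarray:
    """Marker indices of two QTL per linkage group.

    Default placement is deterministic: the markers nearest to 25% and 75%
    of each group's span (25 and 75 cM on the default map).  Passing an
    ``rng`` instead samples two distinct markers uniformly per group.
    """
    if gmap.markers_per_group < 2:
        raise InvalidConfigurationError(
            "each linkage group needs at least 2 markers to carry 2 QTL")
    idx = []
    m = gmap.markers_per_group
    for g in range(gmap.group_count):
        start = g * m
        if rng is not None:
            picks = np.sort(rng.choice(m, size=2, replace=False))
        else:
            picks = [int(round(f * (m - 1))) for f in fractions]
            if picks[0] == picks[1]:  # tiny groups: force distinct loci
                picks[1] = min(picks[0] + 1, m - 1)
                picks[0] = max(picks[1] - 1, 0)
        idx.extend(start + p for p in picks)
    return np.asarray(idx, dtype=int)


@dataclass(frozen=True)
class TraitArchitecture:
    """QTL positions and effects for one simulated trait."""

    qtl_indices: np.ndarray
    weights: np.ndarray
    dominance_ratio: float = 0.0  # d/a, same at every locus
    baseline: float = 0.0  # mu
    additive_unit: float = 1.0  # homozygote effect scale a

    def __post_init__(self):
        object.__setattr__(self, "qtl_indices", np.asarray(self.qtl_indices, dtype=int))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if self.qtl_indices.shape != self.weights.shape:
            raise InvalidConfigurationError("one weight per QTL is required")
        if self.dominance_ratio < 0:
            raise InvalidConfigurationError("dominance ratio d/a must be >= 0")

    @property
    def additive_effects(self) -> np.ndarray:
        """Per-locus homozygote effects a_j = p_j * a."""
        return self.weights * self.additive_unit

    @property
    def dominance_effects(self) -> np.ndarray:
        """Per-locus heterozygote deviations d_j = (d/a) * a_j."""
        return self.dominance_ratio * self.additive_effects

    @classmethod
    def default(cls, gmap: GeneticMap, dominance_ratio: float = 0.0,
                baseline: float = 0.0, additive_unit: float = 1.0,
                rng: np.random.Generator | None = None) -> "TraitArchitecture":
        """Two QTL per group, binomial weights assigned in genome order."""
        qtl = assign_qtl(gmap, rng=rng)
        return cls(qtl, binomial_weights(len(qtl) - 1), dominance_ratio,
                   baseline, additive_unit)


def genetic_value(genotypes_at_qtl: np.ndarray,
                  architecture: TraitArchitecture) -> np.ndarray:
    """True genetic values G_i from QTL dosages (n x n_qtl, values 0/1/2)."""
    d = np.asarray(genotypes_at_qtl)
    if not np.isin(d, (0, 1, 2)).all():
        raise InvalidConfigurationError("QTL dosages must be 0, 1 or 2")
    score = d.astype(float) - 1.0  # +1 / 0 / -1 for AA / Aa / aa
    het = (d == 1)
    return (architecture.baseline
            + score @ architecture.additive_effects
            + het @ architecture.dominance_effects)


def genetic_variance_f2(architecture: TraitArchitecture,
                        population: Population | None = None,
                        method: str = "empirical") -> float:
    """Genetic variance adopted for environmental-noise scaling.

    ``empirical`` (default) takes the sample variance of G over the realised
    base-population individuals; ``closed_form`` returns the expectation for
    an idealised F₂ with independent loci, sum_j (a_j^2 / 2 + d_j^2 / 4).
    The two agree for unlinked loci; linkage between same-group QTL makes
    the realised variance the quantity that actually sets heritability.
    """
    if method == "closed_form":
        a = architecture.additive_effects
        dd = architecture.dominance_effects
        return float(np.sum(a ** 2 / 2.0 + dd ** 2 / 4.0))
    if method != "empirical":
        raise InvalidConfigurationError(f"unknown method {method!r}")
    if population is None or population.size < 2:
        raise InvalidConfigurationError(
            "empirical genetic variance needs a population of size >= 2")
    g = genetic_value(population.dosages()[:, architecture.qtl_indices],
                      architecture)
    return float(np.var(g, ddof=1))


def environmental_variance(sigma2_g: float, h2: float) -> float:
    """sigma2_e = sigma2_g (1 - h2) / h2 for a target broad-sense h2."""
    if not 0.0 < h2 < 1.0:
        raise InvalidConfigurationError("heritability must lie in (0, 1)")
    if sigma2_g <= 0:
        raise InvalidConfigurationError("genetic variance must be positive")
    return sigma2_g * (1.0 - h2) / h2


@dataclass
class PhenotypeSet:
    """True genetic values, environmental effects and phenotypes."""

    genetic_values: np.ndarray
    environmental_effects: np.ndarray
    genetic_variance: float
    environmental_variance: float
    target_h2: float

    @property
    def phenotypes(self) -> np.ndarray:
        return self.genetic_values + self.environmental_effects

    def realized_h2(self) -> float:
        return float(np.var(self.genetic_values, ddof=1)
                     / np.var(self.phenotypes, ddof=1))


def simulate_phenotypes(population: Population,
                        architecture: TraitArchitecture, h2: float,
                        rng: np.random.Generator,
                        sigma2_e: float | None = None) -> PhenotypeSet:
    """Phenotypes P = G + E with E ~ N(0, sigma2_e), independent per individual.

    When ``sigma2_e`` is omitted it is derived from the empirical genetic
    variance of this population via the heritability relation, so the
    cohort is phenotyped at the target h².  Passing a value instead (e.g.
    one computed once from the replicate's F₂) holds the environment
    constant while genetic variance drifts across generations.
    ``sigma2_e = 0`` is an accepted limit (P = G exactly).
    """
    g = genetic_value(population.dosages()[:, architecture.qtl_indices],
                      architecture)
    s2g = float(np.var(g, ddof=1))
    if sigma2_e is None:
        sigma2_e = environmental_variance(s2g, h2)
    elif sigma2_e < 0:
        raise InvalidConfigurationError("environmental variance must be >= 0")
    e = rng.normal(0.0, np.sqrt(sigma2_e), size=population.size)
    return PhenotypeSet(g, e, s2g, float(sigma2_e), h2)
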