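"""The three genomic-selection calibration strategies over the scenario grid.

Strategy 1 trains the additive-dominance G-BLUP model on the F₂ and
predicts the F₂ itself and every advanced generation.  Strategy 2 trains
on each advanced generation n and predicts generations n..4 of the same
mating system (the diagonal is in-sample).  Strategy 3 pools the F₂ with
the first k advanced generations (k = 1, 2, 3 → 1000, 1500, 2000
individuals) and predicts generations k..4.

Reliability is the squared Pearson correlation between the predicted
total genomic value (additive + dominance) and the true genetic value in
the validation cohort.  Each (replicate, architecture) cell is one number;
tables aggregate mean ± SD over replicates.

Reproducing the published tables requires the ``independent_loci``
transmission mode (gametic LD halves every generation under every mating
system; linkage shapes only the F₂ founding), which is therefore the
default here, and the ``f2_hybrid`` backcross scheme (each hybridization
cycle crosses the previous selfing generation back to the F₂ parent
population).  Linked ``meiosis`` and the classic recurrent backcross
chain remain available for biologically standard simulations.  Genotypes
are shared across the six trait architectures within a replicate — the
same populations are scored for six traits — while phenotypes get
architecture-specific noise streams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import gblup
from .errors import InvalidConfigurationError
from .popsim import (SYSTEM_PREFIX, SYSTEMS, Population, advance_series,
                     build_map, f1_genotype, make_f2, make_founders)
from .traits import TraitArchitecture, simulate_phenotypes

__all__ = [
    "ScenarioGrid",
    "simulate_replicate",
    "run_strategy1",
    "run_strategy2",
    "run_strategy3",
    "run_all",
    "aggregate",
    "block_mean",
    "table1",
    "table2",
    "table3",
]

_STAGE = {"f2": 0, "series": 1, "environment": 2, "qtl": 3}
_RECURRENT = ("f2", "f1", "parent1", "parent2")
_MODES = ("independent_loci", "meiosis", "allele_resampling")
_BC_SCHEMES = ("f2_hybrid", "recurrent_chain")


@dataclass(frozen=True)
class ScenarioGrid:
    """Scenario grid and run settings for the simulation study.

    Defaults are the study conditions: six architectures (d/a ∈ {0, 0.5, 1}
    × h² ∈ {0.30, 0.70}), N = 500 per cohort, four advancement generations
    per mating system, ten replicates.
    """

    dominance_ratios: tuple[float, ...] = (0.0, 0.5, 1.0)
    heritabilities: tuple[float, ...] = (0.30, 0.70)
    systems: tuple[str, ...] = ("selfing", "random_mating", "backcross")
    generations: int = 4
    replicates: int = 10
    population_size: int = 500
    group_count: int = 10
    markers_per_group: int = 101
    spacing: float = 1.0
    advancement_mode: str = "independent_loci"
    backcross_scheme: str = "f2_hybrid"
    recurrent_parent: str = "f1"
    hidden_qtl: bool = False
    noise_variance: str = "per_population"
    master_seed: int = 20190117
    reml_method: str = "ai"
    reml_tol: float = 1e-6

    def __post_init__(self):
        for s in self.systems:
            if s not in SYSTEMS:
                raise InvalidConfigurationError(f"unknown system {s!r}")
        for h in self.heritabilities:
            if not 0 < h < 1:
                raise InvalidConfigurationError(
                    f"heritabilities must lie in (0, 1), got {h}")
        for d in self.dominance_ratios:
            if d < 0:
                raise InvalidConfigurationError("dominance_ratios must be >= 0")
        if self.recurrent_parent not in _RECURRENT:
            raise InvalidConfigurationError(
                f"recurrent_parent must be one of {_RECURRENT}")
        if self.advancement_mode not in _MODES:
            raise InvalidConfigurationError(
                f"advancement_mode must be one of {_MODES}")
        if self.backcross_scheme not in _BC_SCHEMES:
            raise InvalidConfigurationError(
                f"backcross_scheme must be one of {_BC_SCHEMES}")
        if self.noise_variance not in ("per_population", "f2_fixed"):
            raise InvalidConfigurationError(
                "noise_variance must be 'per_population' or 'f2_fixed'")
        if self.replicates < 1 or self.population_size < 2 or self.generations < 1:
            raise InvalidConfigurationError("replicates, population_size and "
                                            "generations must be positive")

    def map(self):
        return build_map(self.group_count, self.markers_per_group, self.spacing)

    def architecture(self, dominance_ratio: float) -> TraitArchitecture:
        return TraitArchitecture.default(self.map(), dominance_ratio)

    def labels(self, system: str) -> list[str]:
        p = SYSTEM_PREFIX[system]
        return [f"{p}{i}" for i in range(1, self.generations + 1)]


def _arch_code(d: float, h2: float) -> int:
    return int(round(d * 100)) * 1000 + int(round(h2 * 100))


def _rng(grid: ScenarioGrid, replicate: int, stage: str,
         arch_code: int = 0, extra: int = 0) -> np.random.Generator:
    """Independent stream named by (replicate, stage, architecture, item):
    adding systems or architectures never shifts existing streams."""
    ss = np.random.SeedSequence(grid.master_seed,
                                spawn_key=(replicate, _STAGE[stage],
                                           arch_code, extra))
    return np.random.default_rng(ss)


def _system_mode(grid: ScenarioGrid, system: str) -> str:
    if grid.advancement_mode == "allele_resampling":
        return "allele_resampling" if system == "random_mating" else "meiosis"
    return grid.advancement_mode


def _selfing_series(grid: ScenarioGrid, replicate: int,
                    f2: Population) -> list[Population]:
    rng = _rng(grid, replicate, "series", extra=SYSTEMS.index("selfing"))
    return advance_series(f2, "selfing", grid.generations, rng,
                          mode=_system_mode(grid, "selfing"))


def _backcross_series(grid: ScenarioGrid, replicate: int, f2: Population,
                      selfing: list[Population] | None,
                      recurrent) -> list[Population]:
    """The hybridization series.

    ``f2_hybrid`` (default): Bc_n crosses generation n-1 of the selfing
    series (S₀ = F₂) back to the F₂ parent population — each cohort is
    half fresh F₂ gametes, so the series does not drift away from the
    training population.  ``recurrent_chain`` is the classic backcross
    chain Bc_n = Bc_{n-1} × recurrent parent.
    """
    from .popsim import _gametes_from

    rng = _rng(grid, replicate, "series", extra=SYSTEMS.index("backcross"))
    if grid.backcross_scheme == "recurrent_chain":
        return advance_series(f2, "backcross", grid.generations, rng,
                              mode=_system_mode(grid, "backcross"),
                              recurrent=recurrent)
    gmap = f2.map
    n = f2.size
    linked = _system_mode(grid, "backcross") == "meiosis"
    sources = [f2] + (selfing or [])
    out = []
    for g in range(1, grid.generations + 1):
        src = sources[g - 1]
        ga = _gametes_from(src.haplotypes, rng.integers(src.size, size=n),
                           gmap, rng, linked)
        gb = _gametes_from(f2.haplotypes, rng.integers(f2.size, size=n),
                           gmap, rng, linked)
        out.append(Population(np.stack([ga, gb], axis=1), f"Bc{g}",
                              "backcross", gmap))
    return out


def simulate_replicate(grid: ScenarioGrid, replicate: int) -> dict[str, Population]:
    """All cohorts of one replicate, keyed by generation label ('F2', 'S1', ...)."""
    gmap = grid.map()
    p1, p2 = make_founders(gmap)
    f2 = make_f2(p1, p2, grid.population_size, gmap,
                 _rng(grid, replicate, "f2"))
    pops = {"F2": f2}
    recurrent = {"f2": f2, "f1": f1_genotype(gmap),
                 "parent1": p1, "parent2": p2}[grid.recurrent_parent]
    selfing = None
    need_selfing = ("selfing" in grid.systems
                    or ("backcross" in grid.systems
                        and grid.backcross_scheme == "f2_hybrid"))
    if need_selfing:
        selfing = _selfing_series(grid, replicate, f2)
        if "selfing" in grid.systems:
            for pop in selfing:
                pops[pop.generation_label] = pop
    if "random_mating" in grid.systems:
        rng = _rng(grid, replicate, "series",
                   extra=SYSTEMS.index("random_mating"))
        for pop in advance_series(f2, "random_mating", grid.generations, rng,
                                  mode=_system_mode(grid, "random_mating")):
            pops[pop.generation_label] = pop
    if "backcross" in grid.systems:
        for pop in _backcross_series(grid, replicate, f2, selfing, recurrent):
            pops[pop.generation_label] = pop
    return pops


def _phenotype_all(grid: ScenarioGrid, replicate: int,
                   pops: dict[str, Population], arch: TraitArchitecture,
                   h2: float) -> dict:
    """Phenotype every cohort.

    With ``noise_variance="per_population"`` (default) the environmental
    variance is recalibrated from each cohort's own realised genetic
    variance, so every generation is phenotyped at the target h²; with
    ``"f2_fixed"`` it is set once from the replicate's F₂ and held
    constant, so h² drifts as genetic variance changes under inbreeding.
    """
    code = _arch_code(arch.dominance_ratio, h2)
    f2_set = simulate_phenotypes(pops["F2"], arch, h2,
                                 _rng(grid, replicate, "environment", code, 0))
    s2e = None if grid.noise_variance == "per_population" \
        else f2_set.environmental_variance
    out = {"F2": f2_set}
    order = ["F2"] + [f"{SYSTEM_PREFIX[s]}{i}" for s in SYSTEMS
                      for i in range(1, grid.generations + 1)]
    for label, pop in pops.items():
        if label == "F2":
            continue
        out[label] = simulate_phenotypes(
            pop, arch, h2,
            _rng(grid, replicate, "environment", code, order.index(label)),
            sigma2_e=s2e)
    return out


def _model_dosages(grid: ScenarioGrid, pop: Population,
                   arch: TraitArchitecture) -> np.ndarray:
    d = pop.dosages()
    if grid.hidden_qtl:
        keep = np.setdiff1d(np.arange(pop.map.n_markers), arch.qtl_indices)
        d = d[:, keep]
    return d


def _fit(grid: ScenarioGrid, y: np.ndarray, dosages: np.ndarray) -> gblup.MarkerModel:
    return gblup.fit(y, dosages, method=grid.reml_method, tol=grid.reml_tol)


def _iter_archs(grid: ScenarioGrid):
    for d in grid.dominance_ratios:
        arch = grid.architecture(d)
        for h2 in grid.heritabilities:
            yield arch, h2


def run_strategy1(grid: ScenarioGrid) -> pd.DataFrame:
    """Train on F₂; validate on F₂ and every advanced generation."""
    rows = []
    for rep in range(grid.replicates):
        pops = simulate_replicate(grid, rep)
        for arch, h2 in _iter_archs(grid):
            phen = _phenotype_all(grid, rep, pops, arch, h2)
            model = _fit(grid, phen["F2"].phenotypes,
                         _model_dosages(grid, pops["F2"], arch))
            targets = ["F2"] + [lab for s in grid.systems
                                for lab in grid.labels(s)]
            for lab in targets:
                pred = model.predict(_model_dosages(grid, pops[lab], arch))
                rows.append({
                    "strategy": 1, "replicate": rep,
                    "d": arch.dominance_ratio, "h2": h2,
                    "system": pops[lab].system if lab != "F2" else "base",
                    "training": "F2", "validation": lab,
                    "reliability": gblup.reliability(
                        pred, phen[lab].genetic_values),
                })
    return pd.DataFrame(rows)


def run_strategy2(grid: ScenarioGrid) -> pd.DataFrame:
    """Train on generation n; validate on generations n..4 (same system)."""
    rows = []
    for rep in range(grid.replicates):
        pops = simulate_replicate(grid, rep)
        for arch, h2 in _iter_archs(grid):
            phen = _phenotype_all(grid, rep, pops, arch, h2)
            for system in grid.systems:
                labels = grid.labels(system)
                for i, train in enumerate(labels):
                    model = _fit(grid, phen[train].phenotypes,
                                 _model_dosages(grid, pops[train], arch))
                    for val in labels[i:]:
                        pred = model.predict(
                            _model_dosages(grid, pops[val], arch))
                        rows.append({
                            "strategy": 2, "replicate": rep,
                            "d": arch.dominance_ratio, "h2": h2,
                            "system": system, "training": train,
                            "validation": val,
                            "reliability": gblup.reliability(
                                pred, phen[val].genetic_values),
                        })
    return pd.DataFrame(rows)


def run_strategy3(grid: ScenarioGrid) -> pd.DataFrame:
    """Multigenerational training: pool F₂ with the first k generations
    (k = 1..generations-1) and validate on generations k..4."""
    rows = []
    for rep in range(grid.replicates):
        pops = simulate_replicate(grid, rep)
        for arch, h2 in _iter_archs(grid):
            phen = _phenotype_all(grid, rep, pops, arch, h2)
            for system in grid.systems:
                labels = grid.labels(system)
                for k in range(1, grid.generations):
                    pool = ["F2"] + labels[:k]
                    train_label = "+".join(pool)
                    dos = np.vstack([_model_dosages(grid, pops[l], arch)
                                     for l in pool])
                    y = np.concatenate([phen[l].phenotypes for l in pool])
                    model = _fit(grid, y, dos)
                    for val in labels[k - 1:]:
                        pred = model.predict(
                            _model_dosages(grid, pops[val], arch))
                        rows.append({
                            "strategy": 3, "replicate": rep,
                            "d": arch.dominance_ratio, "h2": h2,
                            "system": system, "training": train_label,
                            "n_training": len(y), "validation": val,
                            "reliability": gblup.reliability(
                                pred, phen[val].genetic_values),
                        })
    return pd.DataFrame(rows)


def run_all(grid: ScenarioGrid) -> dict[int, pd.DataFrame]:
    return {1: run_strategy1(grid), 2: run_strategy2(grid),
            3: run_strategy3(grid)}


_CELL = ["strategy", "d", "h2", "system", "training", "validation"]


def aggregate(results: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean ± SD over replicates (SD absent for one replicate)."""
    g = results.groupby(_CELL, sort=False)["reliability"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan,
                n_replicates="count").reset_index()
    return out


def block_mean(results: pd.DataFrame, strategy: int, system: str, d: float,
               h2: float, validations: list[str] | None = None) -> float:
    """Mean over a table block: replicate-mean per cell, then cell average."""
    sel = results[(results["strategy"] == strategy)
                  & (results["system"] == system)
                  & (results["d"] == d) & (results["h2"] == h2)]
    if validations is not None:
        sel = sel[sel["validation"].isin(validations)]
    cells = sel.groupby(["training", "validation"])["reliability"].mean()
    return float(cells.mean())


def table1(results: pd.DataFrame, h2: float, grid: ScenarioGrid) -> pd.DataFrame:
    """Strategy-1 layout: rows = dominance level, columns = F₂, each
    generation of each system and the per-system 4-generation mean."""
    agg = aggregate(results[(results["strategy"] == 1)
                            & (results["h2"] == h2)])
    rows = {}
    for d in sorted(agg["d"].unique()):
        sub = agg[agg["d"] == d].set_index("validation")["mean"]
        row = {"F2": sub.get("F2", np.nan)}
        for system in grid.systems:
            labels = grid.labels(system)
            for lab in labels:
                row[lab] = sub.get(lab, np.nan)
            row[f"{SYSTEM_PREFIX[system]}_mean"] = float(
                np.mean([sub.get(lab, np.nan) for lab in labels]))
        rows[d] = row
    out = pd.DataFrame(rows).T
    out.index.name = "d"
    return out


def table2(results: pd.DataFrame, d: float, h2: float,
           grid: ScenarioGrid) -> pd.DataFrame:
    """Strategy-2 triangular layout: training generation × validation."""
    agg = aggregate(results[(results["strategy"] == 2) & (results["d"] == d)
                            & (results["h2"] == h2)])
    labels = [lab for s in grid.systems for lab in grid.labels(s)]
    out = pd.DataFrame(np.nan, index=labels, columns=labels)
    for _, r in agg.iterrows():
        out.loc[r["training"], r["validation"]] = r["mean"]
    out.index.name = "training"
    return out


def table3(results: pd.DataFrame, h2: float, grid: ScenarioGrid) -> pd.DataFrame:
    """Strategy-3 layout: pooled training set × validation generation,
    one block per (system, dominance level)."""
    agg = aggregate(results[(results["strategy"] == 3)
                            & (results["h2"] == h2)])
    frames = []
    for system in grid.systems:
        for d in sorted(agg["d"].unique()):
            sub = agg[(agg["system"] == system) & (agg["d"] == d)]
            piv = sub.pivot(index="training", columns="validation",
                            values="mean")
            piv.insert(0, "d", d)
            piv.insert(0, "system", system)
            frames.append(piv)
    return pd.concat(frames)
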