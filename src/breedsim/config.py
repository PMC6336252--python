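"""Run configuration: YAML loading with defaults, validation, hashing,
and deterministic miniature fixtures for tests and examples."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import InvalidConfigurationError
from .popsim import build_map, make_f2, make_founders
from .strategies import ScenarioGrid

__all__ = ["RunConfig", "load_config", "save_config", "config_hash",
           "make_fixture"]


@dataclass(frozen=True)
class RunConfig:
    """A scenario grid plus output settings; fully serialisable, and a
    saved config + seed reproduces a run bit-for-bit."""

    grid: ScenarioGrid = ScenarioGrid()
    output_dir: str = "breedsim_out"
    export_vcf: bool = False
    export_heatmaps: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self.grid)
        d.update(output_dir=self.output_dir, export_vcf=self.export_vcf,
                 export_heatmaps=self.export_heatmaps)
        return d


_GRID_FIELDS = {f.name for f in dataclasses.fields(ScenarioGrid)}
_TOP_FIELDS = {"output_dir", "export_vcf", "export_heatmaps"}
_LIST_FIELDS = {"dominance_ratios", "heritabilities", "systems"}


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load a YAML config; absent keys fall back to the study defaults.

    Unknown keys raise a warning; invalid values raise an error naming the
    offending key.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise InvalidConfigurationError("config must be a mapping")
            data = loaded
    if overrides:
        data.update(overrides)
    grid_kwargs, top_kwargs = {}, {}
    for key, value in data.items():
        if key in _GRID_FIELDS:
            grid_kwargs[key] = tuple(value) if key in _LIST_FIELDS else value
        elif key in _TOP_FIELDS:
            top_kwargs[key] = value
        else:
            warnings.warn(f"unknown config key {key!r} ignored", stacklevel=2)
    try:
        grid = ScenarioGrid(**grid_kwargs)
    except (InvalidConfigurationError, TypeError) as exc:
        raise InvalidConfigurationError(str(exc)) from exc
    return RunConfig(grid=grid, **top_kwargs)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def config_hash(config: RunConfig) -> str:
    """Short stable digest of the full configuration (embedded in outputs)."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def make_fixture(kind: str, seed: int = 0):
    """Deterministic miniature instances for tests and examples.

    tiny_genome
        (map, Population): 1 linkage group × 5 markers, N = 20 F₂.
    two_locus
        (2n × 2) gamete matrix with known haplotype counts
        (6 AB, 2 Ab, 2 aB, 6 ab over 16 gametes) for LD hand-checks.
    toy_training
        (dosages, phenotypes): 5 individuals × 3 markers for the ridge
        oracle, with a fixed printed dosage matrix.
    """
    if kind == "tiny_genome":
        gmap = build_map(1, 5, 1.0)
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
        p1, p2 = make_founders(gmap)
        return gmap, make_f2(p1, p2, 20, gmap, rng)
    if kind == "two_locus":
        counts = {(1, 1): 6, (1, 0): 2, (0, 1): 2, (0, 0): 6}
        return np.array([hap for hap, k in counts.items() for _ in range(k)],
                        dtype=np.int8)
    if kind == "toy_training":
        dosages = np.array([[2, 1, 0],
                            [1, 1, 2],
                            [0, 2, 1],
                            [2, 0, 1],
                            [1, 2, 2]], dtype=np.int8)
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(8,)))
        y = dosages @ np.array([0.5, -0.2, 0.1]) + rng.normal(0, 0.3, 5)
        return dosages, y
    raise InvalidConfigurationError(f"unknown fixture kind {kind!r}")
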