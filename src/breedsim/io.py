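"""File input/output: dosage and map CSVs, phased VCF export, phenotype,
architecture, LD and reliability tables, and marker-model dumps.

Every CSV starts with ``#`` comment lines embedding the config hash and
seed so a saved table identifies the run that produced it; read them back
with ``pandas.read_csv(..., comment="#")``.  VCF positions use the 1 cM ≈
1 Mb convention (POS = within-group cM × 1e6 + 1).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidConfigurationError
from .gblup import MarkerModel
from .popsim import GeneticMap, Population, build_map

__all__ = [
    "write_dosage_csv", "read_dosage_csv", "write_map_csv", "write_vcf",
    "read_vcf", "write_phenotypes_csv", "write_architecture_csv",
    "write_ld_csv", "write_reliability_csv", "write_model",
    "read_phenotypes_csv",
]


def _header(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in sorted(meta.items()))


def _write_frame(df: pd.DataFrame, path: str | Path, meta: dict | None,
                 index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(_header(meta))
        df.to_csv(fh, index=index)


def write_dosage_csv(population: Population, path: str | Path,
                     meta: dict | None = None) -> None:
    """Individuals × markers dosage matrix (values 0/1/2)."""
    gmap = population.map
    df = pd.DataFrame(population.dosages(), columns=list(gmap.marker_ids))
    df.insert(0, "individual_id",
              [f"{population.generation_label}_{i + 1}"
               for i in range(population.size)])
    _write_frame(df, path, meta)


def read_dosage_csv(path: str | Path) -> tuple[list[str], np.ndarray]:
    """(individual ids, dosage matrix) from a dosage CSV."""
    df = pd.read_csv(path, comment="#")
    ids = df["individual_id"].astype(str).tolist()
    return ids, df.drop(columns=["individual_id"]).to_numpy(dtype=np.int8)


def write_map_csv(gmap: GeneticMap, path: str | Path,
                  meta: dict | None = None) -> None:
    df = pd.DataFrame({"marker": list(gmap.marker_ids),
                       "group": gmap.group_of_marker + 1,
                       "position_cM": gmap.positions})
    _write_frame(df, path, meta)


def write_vcf(population: Population, path: str | Path,
              meta: dict | None = None) -> None:
    """Phased VCF (GT field, '|' separator), REF=A ALT=T, allele 1 = ALT."""
    gmap = population.map
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    names = [f"{population.generation_label}_{i + 1}"
             for i in range(population.size)]
    h = population.haplotypes
    with open(path, "w", newline="") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=breedsim\n")
        for k, v in sorted((meta or {}).items()):
            fh.write(f"##breedsim_{k}={v}\n")
        for g in range(gmap.group_count):
            fh.write(f"##contig=<ID={g + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        for j in range(gmap.n_markers):
            pos = int(round(gmap.positions[j] * 1_000_000)) + 1
            gts = "\t".join(f"{h[i, 0, j]}|{h[i, 1, j]}"
                            for i in range(population.size))
            fh.write(f"{gmap.group_of_marker[j] + 1}\t{pos}\t"
                     f"{gmap.marker_ids[j]}\tA\tT\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path: str | Path) -> tuple[list[str], np.ndarray, GeneticMap]:
    """(sample names, dosage matrix, reconstructed map) from a breedsim VCF.

    Intended for feeding user genotypes to the prediction module; dosage is
    the ALT-allele count from GT.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    rows, groups, positions = [], [], []
    for rec in vf:
        groups.append(int(rec.chrom))
        positions.append(rec.pos)
        rows.append([sum(rec.samples[s]["GT"]) for s in samples])
    vf.close()
    dos = np.asarray(rows, dtype=np.int8).T
    n_groups = len(set(groups))
    per_group = len(groups) // n_groups
    if per_group * n_groups != len(groups):
        raise InvalidConfigurationError("VCF groups are unevenly sized")
    spacing = (positions[1] - positions[0]) / 1e6 if per_group > 1 else 1.0
    return samples, dos, build_map(n_groups, per_group, spacing)


def write_phenotypes_csv(labels: list[str], generation: list[str],
                         phenoset, path: str | Path,
                         meta: dict | None = None) -> None:
    """Columns individual_id, generation, G, E, P."""
    df = pd.DataFrame({"individual_id": labels, "generation": generation,
                       "G": phenoset.genetic_values,
                       "E": phenoset.environmental_effects,
                       "P": phenoset.phenotypes})
    _write_frame(df, path, meta)


def read_phenotypes_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_architecture_csv(architecture, gmap: GeneticMap, path: str | Path,
                           meta: dict | None = None) -> None:
    qtl = architecture.qtl_indices
    df = pd.DataFrame({"qtl_marker": [gmap.marker_ids[i] for i in qtl],
                       "group": gmap.group_of_marker[qtl] + 1,
                       "weight": architecture.weights,
                       "additive_effect": architecture.additive_effects,
                       "dominance_effect": architecture.dominance_effects})
    _write_frame(df, path, meta)


def write_ld_csv(table: pd.DataFrame, path: str | Path,
                 meta: dict | None = None) -> None:
    _write_frame(table, path, meta)


def write_reliability_csv(table: pd.DataFrame, path: str | Path,
                          meta: dict | None = None) -> None:
    _write_frame(table, path, meta)


def write_model(model: MarkerModel, csv_path: str | Path,
                meta_path: str | Path | None = None,
                meta: dict | None = None) -> None:
    """Per-marker effects CSV plus a JSON metadata block."""
    df = pd.DataFrame({"marker": np.arange(model.n_markers),
                       "training_p": model.training_freqs,
                       "additive_effect": model.additive_effects,
                       "dominance_effect": model.dominance_effects})
    _write_frame(df, csv_path, meta)
    if meta_path is not None:
        vc = model.variance_components
        blob = {"intercept": model.intercept, "n_training": model.n_training,
                "sigma2_a": vc.sigma2_a, "sigma2_d": vc.sigma2_d,
                "sigma2_e": vc.sigma2_e, "converged": vc.converged,
                "n_iterations": vc.n_iterations, "method": vc.method,
                **(meta or {})}
        Path(meta_path).write_text(json.dumps(blob, indent=2, sort_keys=True))
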