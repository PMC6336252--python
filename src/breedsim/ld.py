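"""Linkage disequilibrium: pairwise r² within linkage groups and its decay
across generations.

The primary estimator works on the observed gamete pool (the simulator is
phased): ``D = f(AB) - f(A) f(B)`` over the 2N haplotypes and
``r2 = D^2 / (pA qA pB qB)``.  An EM estimator over the double-heterozygote
phase ambiguity handles unphased dosage data.  Pairs involving a
monomorphic locus have no defined r² and are skipped in summaries (with
counts reported).  Inter-group pairs are excluded: each linkage group is
summarised separately and distances are map distances in cM.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import MonomorphicLocusError
from .popsim import GeneticMap, Population

__all__ = [
    "r2_from_haplotypes",
    "r2_em_unphased",
    "pairwise_r2_matrix",
    "ld_decay_table",
    "adjacent_mean_r2",
    "plot_ld_heatmap",
]


def _as_gametes(haplotypes: np.ndarray) -> np.ndarray:
    h = np.asarray(haplotypes)
    if h.ndim == 3:
        h = h.reshape(-1, h.shape[2])
    return h


def r2_from_haplotypes(haplotypes: np.ndarray, locus_a: int,
                       locus_b: int) -> tuple[float, float]:
    """(D, r2) between two loci from a phased gamete pool.

    ``haplotypes`` is (2n, m) gametes or (n, 2, m) phased individuals.
    """
    h = _as_gametes(haplotypes)
    a = h[:, locus_a].astype(float)
    b = h[:, locus_b].astype(float)
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise MonomorphicLocusError("LD is undefined at a fixed locus")
    d = float((a * b).mean() - pa * pb)
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    return d, float(r2)


def r2_em_unphased(dosages_a: np.ndarray, dosages_b: np.ndarray,
                   tol: float = 1e-8, max_iter: int = 1000) -> tuple[float, float]:
    """Maximum-likelihood (D, r2) from unphased dosages at two loci.

    The only ambiguity in two-locus diploid data is the double
    heterozygote (coupling AB/ab vs repulsion Ab/aB); EM iterates the
    expected coupling fraction until haplotype frequencies change by less
    than ``tol``.  With no double heterozygotes this equals the
    phase-known estimator exactly.
    """
    da = np.asarray(dosages_a, dtype=int)
    db = np.asarray(dosages_b, dtype=int)
    n = da.shape[0]
    pa = da.mean() / 2.0
    pb = db.mean() / 2.0
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise MonomorphicLocusError("LD is undefined at a fixed locus")
    # counts of unambiguous AB haplotypes per individual, and the ambiguous ones
    n_dh = int(((da == 1) & (db == 1)).sum())
    # known AB gametes: each copy of A beyond het pairs... tabulate directly
    # from the 3x3 genotype table.
    counts = np.zeros((3, 3), dtype=float)
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.sum((da == i) & (db == j))
    # haplotype tallies excluding the double heterozygote
    # genotype (i, j) contributes known gametes: e.g. (2,2) -> 2 AB
    known_ab = (2 * counts[2, 2] + counts[2, 1] + counts[1, 2])
    f_ab = pa * pb  # start at linkage equilibrium
    for it in range(max_iter):
        f_a_b = pa - f_ab          # f(Ab)
        f_b_a = pb - f_ab          # f(aB)
        f_ab_low = 1 - pa - pb + f_ab  # f(ab)
        coup = f_ab * f_ab_low
        rep = f_a_b * f_b_a
        frac = coup / (coup + rep) if coup + rep > 0 else 0.5
        new_f_ab = (known_ab + n_dh * frac) / (2.0 * n)
        if abs(new_f_ab - f_ab) < tol:
            f_ab = new_f_ab
            break
        f_ab = new_f_ab
    else:
        warnings.warn("EM for haplotype frequencies did not converge",
                      RuntimeWarning, stacklevel=2)
    d = float(f_ab - pa * pb)
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    return d, float(r2)


def _group_r2(gametes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs r² within one group; returns (r2 matrix, polymorphic mask).

    Entries touching a monomorphic locus are NaN.
    """
    h = gametes.astype(float)
    two_n = h.shape[0]
    p = h.mean(axis=0)
    poly = (p > 0) & (p < 1)
    D = h.T @ h / two_n - np.outer(p, p)
    denom = np.outer(p * (1 - p), p * (1 - p))
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(np.outer(poly, poly), D * D / denom, np.nan)
    return r2, poly


def pairwise_r2_matrix(population: Population, group: int) -> np.ndarray:
    """Within-group pairwise r² matrix (NaN at monomorphic loci)."""
    sl = population.map.group_slice(group)
    r2, _ = _group_r2(population.gametes()[:, sl])
    return r2


def ld_decay_table(populations: list[Population], gmap: GeneticMap,
                   max_distance: float | None = None) -> pd.DataFrame:
    """Mean within-group r² by map distance, per population.

    Returns a tidy frame with columns ``generation, distance_cM, mean_r2,
    n_pairs, n_skipped`` (skipped = pairs with a monomorphic locus).  With
    equally spaced markers each distance bin is an exact multiple of the
    spacing; ``max_distance=0`` yields an empty table.
    """
    rows = []
    m = gmap.markers_per_group
    max_off = m - 1
    if max_distance is not None:
        max_off = min(max_off, int(np.floor(max_distance / gmap.spacing)))
    for pop in populations:
        gam = pop.gametes()
        sums = np.zeros(max_off + 1)
        cnts = np.zeros(max_off + 1, dtype=int)
        skip = np.zeros(max_off + 1, dtype=int)
        for g in range(gmap.group_count):
            r2, _ = _group_r2(gam[:, gmap.group_slice(g)])
            for off in range(1, max_off + 1):
                diag = np.diagonal(r2, offset=off)
                ok = ~np.isnan(diag)
                sums[off] += np.nansum(diag)
                cnts[off] += int(ok.sum())
                skip[off] += int((~ok).sum())
        for off in range(1, max_off + 1):
            rows.append({
                "generation": pop.generation_label,
                "distance_cM": off * gmap.spacing,
                "mean_r2": sums[off] / cnts[off] if cnts[off] else np.nan,
                "n_pairs": cnts[off],
                "n_skipped": skip[off],
            })
    return pd.DataFrame(rows, columns=["generation", "distance_cM", "mean_r2",
                                       "n_pairs", "n_skipped"])


def adjacent_mean_r2(population: Population) -> float:
    """Mean r² over all adjacent within-group marker pairs."""
    tab = ld_decay_table([population], population.map,
                         max_distance=population.map.spacing)
    return float(tab["mean_r2"].iloc[0])


def overall_mean_r2(population: Population,
                    max_distance: float | None = None) -> float:
    """Mean r² over all within-group pairs (optionally distance-limited)."""
    tab = ld_decay_table([population], population.map, max_distance)
    tot = (tab["mean_r2"] * tab["n_pairs"]).sum()
    return float(tot / tab["n_pairs"].sum())


def plot_ld_heatmap(population: Population, path: str) -> None:
    """Genome-wide r² heatmap (within-group blocks; inter-group left blank)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    gmap = population.map
    full = np.full((gmap.n_markers, gmap.n_markers), np.nan)
    for g in range(gmap.group_count):
        sl = gmap.group_slice(g)
        full[sl, sl] = pairwise_r2_matrix(population, g)
    fig, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(full, vmin=0, vmax=1, cmap="viridis", interpolation="nearest")
    ax.set_title(f"r2, {population.generation_label}")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=120)
    plt.close(fig)
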