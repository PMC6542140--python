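"""DIYABC-style summary statistics used as the ABC observation vector.

Within each population: proportion of monomorphic loci, mean and variance
of Nei's unbiased gene diversity over polymorphic loci, and mean gene
diversity over all loci.  A newly founded population is represented by the
reduced pair {proportion monomorphic, mean gene diversity over all loci},
because its recent explosive growth makes the higher moments uninformative.

Between designated population pairs: mean per-locus Weir-Cockerham F_ST,
the proportion of "null" (<= 0) per-locus estimates, and the mean and
variance of the strictly positive remainder.

All statistics are invariant to sample order and to ref/alt relabeling.
The vector ordering is fixed (see :func:`observed_summary`) so observed and
simulated vectors align column-by-column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import MISSING, GenotypeMatrix
from .snp_filtering import pairwise_fst


@dataclass
class PopulationRoles:
    """Which population label plays which role in the four-population
    scenario: two native clusters and the introduced cluster."""

    native1: str
    native2: str
    introduced: str


@dataclass(eq=False)
class SummaryStatVector:
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValueError("names and values must have equal length")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))

    def __len__(self) -> int:
        return self.values.size


def gene_diversity(calls: np.ndarray) -> float:
    """Nei's unbiased gene diversity for one locus within one population.

    ``calls`` are diploid alt-allele counts (0/1/2, MISSING allowed):
    H = n/(n-1) * (1 - p^2 - q^2) over the n non-missing gene copies.
    """
    calls = np.asarray(calls)
    called = calls != MISSING
    n = 2 * int(called.sum())
    if n < 2:
        raise ValueError("gene diversity undefined with < 2 gene copies")
    p = calls[called].sum() / n
    return float(n / (n - 1) * (1.0 - p**2 - (1.0 - p) ** 2))


def _pop_locus_diversity(matrix: GenotypeMatrix, pop: str):
    """Vectorised per-locus gene diversity within ``pop``.

    Returns (H, estimable) where H is NaN at non-estimable loci (< 2 gene
    copies) and ``estimable`` the boolean mask.
    """
    idx = matrix.sample_indices(pop)
    calls = matrix.calls[idx]
    called = calls != MISSING
    n = 2 * called.sum(axis=0).astype(float)
    alt = np.where(called, calls, 0).sum(axis=0)
    estimable = n >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / np.maximum(n, 1)
        h = n / np.maximum(n - 1, 1) * (1.0 - p**2 - (1.0 - p) ** 2)
    h = np.where(estimable, h, np.nan)
    return h, estimable


def within_population_stats(
    matrix: GenotypeMatrix, pop: str, mode: str = "full"
) -> dict[str, float]:
    """Within-population statistics; ``mode`` is ``full`` or ``reduced``.

    "Polymorphic" is judged within the population (gene diversity > 0).
    """
    if mode not in ("full", "reduced"):
        raise ValueError("mode must be 'full' or 'reduced'")
    if matrix.sample_indices(pop).size < 2:
        raise ValueError(f"population {pop!r} needs >= 2 samples")
    h, estimable = _pop_locus_diversity(matrix, pop)
    h_est = h[estimable]
    if h_est.size == 0:
        raise ValueError(f"population {pop!r} has no estimable loci")
    poly = h_est > 0.0
    prop_mono = float(1.0 - poly.mean())
    mean_all = float(h_est.mean())
    if mode == "reduced":
        return {"prop_monomorphic": prop_mono, "mean_gene_div_all": mean_all}
    if poly.sum() == 0:
        warnings.warn(f"population {pop!r}: no polymorphic loci", stacklevel=2)
        mean_poly, var_poly = 0.0, 0.0
    else:
        hp = h_est[poly]
        mean_poly = float(hp.mean())
        var_poly = float(hp.var(ddof=1)) if hp.size > 1 else 0.0
    return {
        "prop_monomorphic": prop_mono,
        "mean_gene_div_polymorphic": mean_poly,
        "var_gene_div_polymorphic": var_poly,
        "mean_gene_div_all": mean_all,
    }


def between_population_stats(
    matrix: GenotypeMatrix, pop_a: str, pop_b: str
) -> dict[str, float]:
    """Pairwise F_ST statistics over estimable loci.

    "Null" means a per-locus Weir-Cockerham estimate <= 0.  Non-estimable
    loci (pooled-monomorphic) are excluded.  Degenerate summaries (no
    non-null loci) report 0 so simulated vectors stay total.
    """
    per_locus, _ = pairwise_fst(matrix, pop_a, pop_b)
    vals = per_locus[~np.isnan(per_locus)]
    if vals.size == 0:
        return {
            "mean_fst": 0.0,
            "prop_null_fst": 1.0,
            "mean_nonnull_fst": 0.0,
            "var_nonnull_fst": 0.0,
        }
    nonnull = vals[vals > 0.0]
    return {
        "mean_fst": float(vals.mean()),
        "prop_null_fst": float((vals <= 0.0).mean()),
        "mean_nonnull_fst": float(nonnull.mean()) if nonnull.size else 0.0,
        "var_nonnull_fst": float(nonnull.var(ddof=1)) if nonnull.size > 1 else 0.0,
    }


_WITHIN_FULL = (
    "prop_monomorphic",
    "mean_gene_div_polymorphic",
    "var_gene_div_polymorphic",
    "mean_gene_div_all",
)
_WITHIN_REDUCED = ("prop_monomorphic", "mean_gene_div_all")
_BETWEEN = ("mean_fst", "prop_null_fst", "mean_nonnull_fst", "var_nonnull_fst")


def summary_stat_names(roles: PopulationRoles) -> list[str]:
    names = []
    names += [f"N1_{s}" for s in _WITHIN_FULL]
    names += [f"N2_{s}" for s in _WITHIN_FULL]
    names += [f"I_{s}" for s in _WITHIN_REDUCED]
    names += [f"N1N2_{s}" for s in _BETWEEN]
    names += [f"N1I_{s}" for s in _BETWEEN]
    return names


def observed_summary(
    matrix: GenotypeMatrix, roles: PopulationRoles
) -> SummaryStatVector:
    """Assemble the full 18-component ordered statistic vector.

    Full within-population statistics for the two native clusters, the
    reduced pair for the introduced cluster, and between-population F_ST
    blocks for the two pairs that diverged directly from each other
    (native1/native2 and native1/introduced).
    """
    for pop in (roles.native1, roles.native2, roles.introduced):
        matrix.sample_indices(pop)  # raises a labeled error if absent
    values: list[float] = []
    values += within_population_stats(matrix, roles.native1, "full").values()
    values += within_population_stats(matrix, roles.native2, "full").values()
    values += within_population_stats(matrix, roles.introduced, "reduced").values()
    values += between_population_stats(matrix, roles.native1, roles.native2).values()
    values += between_population_stats(matrix, roles.native1, roles.introduced).values()
    return SummaryStatVector(names=summary_stat_names(roles), values=np.array(values))
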