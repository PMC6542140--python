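"""RAD-seq SNP quality filters and the Weir-Cockerham F_ST estimator.

The filter pipeline mirrors standard reduced-representation practice:
per-genotype depth masking, per-population call-rate, minor allele
frequency, physical spacing between retained sites, and removal of
high-missingness samples.  Two presets are provided: the stringent one
used for population-structure work (80% call rate, MAF 1%) and the ABC
variant (90% call rate, MAF 0.5%).

Every filter is a projection (idempotent) and only changes membership,
never the retained genotype values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


class FilterError(ValueError):
    pass


@dataclass
class FilterConfig:
    min_depth: int = 3
    min_call_rate_per_pop: float = 0.80
    min_maf: float = 0.01
    min_spacing_bp: int = 5000
    max_sample_missing: float = 0.30

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_call_rate_per_pop <= 1.0:
            raise ValueError("min_call_rate_per_pop must be in [0, 1]")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")
        if not 0.0 <= self.max_sample_missing <= 1.0:
            raise ValueError("max_sample_missing must be in [0, 1]")
        if self.min_spacing_bp < 0:
            raise ValueError("min_spacing_bp must be >= 0")

    @classmethod
    def abc_variant(cls) -> "FilterConfig":
        """Looser MAF, tighter call rate: the demographic-inference preset."""
        return cls(min_call_rate_per_pop=0.90, min_maf=0.005)


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------

def mask_low_depth(matrix: GenotypeMatrix, min_depth: int) -> GenotypeMatrix:
    """Set calls backed by fewer than ``min_depth`` reads to MISSING."""
    if min_depth <= 0:
        return matrix
    if matrix.depth is None:
        raise FilterError(
            "matrix carries no depth information; skip the depth-masking stage"
        )
    calls = matrix.calls.copy()
    calls[matrix.depth < min_depth] = MISSING
    return GenotypeMatrix(
        sample_ids=list(matrix.sample_ids),
        pop_labels=list(matrix.pop_labels),
        loci=list(matrix.loci),
        calls=calls,
        depth=matrix.depth.copy(),
    )


def minor_allele_frequency(matrix: GenotypeMatrix, locus_index: int) -> float:
    """MAF over non-missing gene copies (2 per genotyped diploid)."""
    col = matrix.calls[:, locus_index]
    called = col != MISSING
    n_copies = 2 * int(called.sum())
    if n_copies == 0:
        raise FilterError(f"locus index {locus_index}: all calls missing, MAF undefined")
    p = col[called].sum() / n_copies
    return float(min(p, 1.0 - p))


def _maf_vector(matrix: GenotypeMatrix) -> np.ndarray:
    """Vectorised MAF per locus; NaN where no calls."""
    called = matrix.calls != MISSING
    copies = 2 * called.sum(axis=0)
    alt = np.where(called, matrix.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(copies > 0, alt / np.maximum(copies, 1), np.nan)
    return np.minimum(p, 1.0 - p)


def filter_by_maf(matrix: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    maf = _maf_vector(matrix)
    keep = np.flatnonzero(~np.isnan(maf) & (maf >= min_maf))
    return matrix.take_loci(keep)


def filter_by_call_rate(
    matrix: GenotypeMatrix, min_call_rate_per_pop: float
) -> GenotypeMatrix:
    """Keep loci genotyped in at least the given fraction of every population."""
    if not matrix.populations:
        raise FilterError("no populations present")
    called = matrix.calls != MISSING
    keep = np.ones(matrix.n_loci, dtype=bool)
    for pop in matrix.populations:
        idx = matrix.sample_indices(pop)
        rate = called[idx].mean(axis=0)
        keep &= rate >= min_call_rate_per_pop
    return matrix.take_loci(np.flatnonzero(keep))


def thin_by_spacing(matrix: GenotypeMatrix, min_spacing_bp: int) -> GenotypeMatrix:
    """Greedy left-to-right thinning: keep a locus iff it is at least
    ``min_spacing_bp`` from the last kept locus on the same contig."""
    if min_spacing_bp <= 0:
        return matrix
    keep = []
    last: dict[str, int] = {}
    for j, loc in enumerate(matrix.loci):
        prev = last.get(loc.contig)
        if prev is None or loc.pos - prev >= min_spacing_bp:
            keep.append(j)
            last[loc.contig] = loc.pos
    return matrix.take_loci(np.array(keep, dtype=int))


def drop_high_missing_samples(
    matrix: GenotypeMatrix, max_sample_missing: float
) -> GenotypeMatrix:
    """Remove samples whose missing-call fraction exceeds the threshold."""
    if matrix.n_loci == 0:
        return matrix
    miss = (matrix.calls == MISSING).mean(axis=1)
    keep = np.flatnonzero(miss <= max_sample_missing)
    if keep.size == 0:
        raise FilterError("all samples exceed the missing-data threshold")
    return matrix.take_samples(keep)


def apply_filter_pipeline(
    matrix: GenotypeMatrix,
    config: FilterConfig,
    return_counts: bool = False,
):
    """Depth mask -> call rate -> MAF -> spacing -> sample drop.

    Logs survivor counts after each stage; with ``return_counts=True`` also
    returns the stage table as a list of (stage, n_samples, n_loci).
    """
    counts = [("input", matrix.n_samples, matrix.n_loci)]
    m = matrix
    if config.min_depth > 0 and m.depth is not None:
        m = mask_low_depth(m, config.min_depth)
    counts.append(("depth_mask", m.n_samples, m.n_loci))
    m = filter_by_call_rate(m, config.min_call_rate_per_pop)
    counts.append(("call_rate", m.n_samples, m.n_loci))
    m = filter_by_maf(m, config.min_maf)
    counts.append(("maf", m.n_samples, m.n_loci))
    m = thin_by_spacing(m, config.min_spacing_bp)
    counts.append(("spacing", m.n_samples, m.n_loci))
    m = drop_high_missing_samples(m, config.max_sample_missing)
    counts.append(("sample_missing", m.n_samples, m.n_loci))
    log.info(
        "filter pipeline: %s",
        " -> ".join(f"{s}: {ns} samples x {nl} loci" for s, ns, nl in counts),
    )
    if return_counts:
        return m, counts
    return m


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) F_ST
# ---------------------------------------------------------------------------

def _wc_components(
    matrix: GenotypeMatrix, pop_a: str, pop_b: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus variance components (a, b, c) of the WC84 estimator,
    for two populations and biallelic loci.  NaN where not estimable."""
    comps = []
    for pop in (pop_a, pop_b):
        idx = matrix.sample_indices(pop)
        calls = matrix.calls[idx]
        called = calls != MISSING
        n = called.sum(axis=0).astype(float)  # genotyped individuals
        alt = np.where(called, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / (2 * np.maximum(n, 1)), np.nan)
            h = np.where(n > 0, np.where(called, calls == 1, False).sum(axis=0) / np.maximum(n, 1), np.nan)
        comps.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comps

    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
    # not estimable: a population with < 1 genotyped individual, nbar <= 1,
    # or nc <= 0
    bad = (n1 < 1) | (n2 < 1) | (nbar <= 1) | ~(nc > 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def pairwise_fst(
    matrix: GenotypeMatrix, pop_a: str, pop_b: str
) -> tuple[np.ndarray, float]:
    """Per-locus Weir & Cockerham theta-hat and the multi-locus
    ratio-of-averages mean.

    Per-locus values are NaN where the estimator is undefined (monomorphic
    in the pooled pair, or too few genotyped samples).  Negative values are
    retained, not clipped.
    """
    a, b, c = _wc_components(matrix, pop_a, pop_b)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = np.where(denom != 0, a / denom, np.nan)
    ok = ~np.isnan(denom) & (denom != 0)
    mean = float(np.nansum(a[ok]) / np.nansum(denom[ok])) if ok.any() else float("nan")
    return per_locus, mean
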