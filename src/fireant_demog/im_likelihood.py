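"""Maximum-likelihood comparison of complete isolation vs isolation with
migration on three-sequence alignments.

Each locus is an alignment of two ingroup sequences (from S. invicta and/or
S. richteri) and an outgroup (S. fugax).  The likelihood of a locus is the
integral, over gene-tree topologies and the two coalescence times, of the
multispecies-coalescent gene-tree density times the JC69 probability of
the alignment given the tree:

    L_locus = sum_topo  integral f(topo, t1, t0) * P(alignment | tree) dt1 dt0

Under complete isolation the two ingroup lineages can only coalesce in
their own species (same-species pairs), in the ingroup ancestor between
tau_ir and tau_root, or in the root.  Under isolation with migration the
lineages additionally move between the two species before tau_ir; their
joint location follows a 3-state continuous-time Markov chain (both in
invicta / split / both in richteri) with coalescence as an absorbing event.

Both time integrals use Gaussian quadrature in the transformed variable
v = exp(-4t/3), the natural scale of the JC69 kernel: semi-infinite
exponential-weight integrals become exact Beta-weight Gauss-Jacobi rules,
finite ones Gauss-Legendre with the weight evaluated explicitly (see
``_exp_nodes``); the migration-phase integral over (0, tau_ir) is mapped
linearly.

Because sequences are exchangeable within a site-pattern class under JC69,
an alignment enters the likelihood only through its five pattern counts
(all equal; a=b; a=out; b=out; all different), with sites containing N
skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from functools import lru_cache

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .coalescent_sim import IMParams, TOPO_A_OUT, TOPO_B_OUT, TOPO_INGROUP
from .io_formats import TripletAlignment, TripletDataset

#: observed-class -> base-class column permutation per cherry topology.
#: Base classes are computed with the cherry tips first: (0) all same,
#: (1) cherry pair equal, (2) first cherry tip = odd tip, (3) second cherry
#: tip = odd tip, (4) all different.
_PERMS = {
    TOPO_INGROUP: np.array([0, 1, 2, 3, 4]),
    TOPO_A_OUT: np.array([0, 2, 1, 3, 4]),
    TOPO_B_OUT: np.array([0, 2, 3, 1, 4]),
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

#: representative site patterns (x, y, z) for the five pattern classes
_PATTERN_REPS = [(0, 0, 0), (0, 0, 1), (0, 1, 0), (1, 0, 0), (0, 1, 2)]
_STATES = np.arange(4)
_MASK_Z = np.array([[r == z for r in _STATES] for (_, _, z) in _PATTERN_REPS])
_MASK_RI = np.equal.outer(_STATES, _STATES)
_MASK_X = np.array([[i == x for i in _STATES] for (x, _, _) in _PATTERN_REPS])
_MASK_Y = np.array([[i == y for i in _STATES] for (_, y, _) in _PATTERN_REPS])


@dataclass
class IMFitConfig:
    quadrature_points: int = 16
    n_starts: int = 3
    seed: int = 0
    optimizer_tol: float = 1e-7
    max_iter: int = 200

    def __post_init__(self) -> None:
        if self.quadrature_points < 2:
            raise ValueError("quadrature_points must be >= 2")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass
class FitResult:
    model: str  # "null" | "im"
    params: IMParams
    loglik: float
    starts: list[dict] = field(default_factory=list)
    converged: bool = True


# ---------------------------------------------------------------------------
# JC69 primitives
# ---------------------------------------------------------------------------

def jc69_transition(t: float) -> np.ndarray:
    """JC69 transition matrix for branch length t (expected substitutions
    per site): P(i->i) = 1/4 + 3/4 exp(-4t/3), off-diagonal
    1/4 - 1/4 exp(-4t/3)."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    e = np.exp(-4.0 * t / 3.0)
    same = 0.25 + 0.75 * e
    diff = 0.25 - 0.25 * e
    return np.full((4, 4), diff) + np.eye(4) * (same - diff)


def _jc_pattern_logprobs(t1: np.ndarray, t0: np.ndarray) -> np.ndarray:
    """Log probabilities of the five site-pattern classes for a rooted
    triplet with cherry tips (x, y) at time t1 and odd tip z joining at the
    root t0.  Returns shape (..., 5): classes (xxx, xy-equal, x=z, y=z,
    all-different), each the probability of one representative site
    pattern."""
    t1 = np.asarray(t1, dtype=float)
    t0 = np.asarray(t0, dtype=float)
    e1 = np.exp(-4.0 * t1 / 3.0)
    s1, d1 = 0.25 + 0.75 * e1, 0.25 - 0.25 * e1
    em = np.exp(-4.0 * (t0 - t1) / 3.0)
    sm, dm = 0.25 + 0.75 * em, 0.25 - 0.25 * em
    e0 = np.exp(-4.0 * t0 / 3.0)
    s0, d0 = 0.25 + 0.75 * e0, 0.25 - 0.25 * e0

    shp = t1.shape + (1, 1)
    sz = np.where(_MASK_Z, s0.reshape(shp), d0.reshape(shp))  # (..., 5, 4) over r
    sm_ = np.where(_MASK_RI, sm.reshape(shp), dm.reshape(shp))  # (..., 4, 4) r x i
    sx = np.where(_MASK_X, s1.reshape(shp), d1.reshape(shp))  # (..., 5, 4) over i
    sy = np.where(_MASK_Y, s1.reshape(shp), d1.reshape(shp))
    p = 0.25 * np.einsum("...kr,...ri,...ki,...ki->...k", sz, sm_, sx, sy)
    # zero-branch degenerate trees give exactly-zero pattern classes; the
    # floor keeps 0 * log(0) products well-defined for absent classes
    return np.log(np.maximum(p, 1e-300))


_BASE_LUT = np.full(256, -1, dtype=np.int8)
for _c, _i in _BASE_INDEX.items():
    _BASE_LUT[ord(_c)] = _i


def pattern_counts(triplet: TripletAlignment) -> np.ndarray:
    """Counts of the five site-pattern classes of (a, b, out); sites with N
    in any sequence are skipped.  Cached on the alignment object."""
    cached = getattr(triplet, "_pattern_counts", None)
    if cached is not None:
        return cached
    a = _BASE_LUT[np.frombuffer(triplet.seq_a.encode(), dtype=np.uint8)]
    b = _BASE_LUT[np.frombuffer(triplet.seq_b.encode(), dtype=np.uint8)]
    o = _BASE_LUT[np.frombuffer(triplet.seq_out.encode(), dtype=np.uint8)]
    ok = (a >= 0) & (b >= 0) & (o >= 0)
    a, b, o = a[ok], b[ok], o[ok]
    ab, ao, bo = a == b, a == o, b == o
    cls = np.full(a.shape, 4)
    cls[ab & ao] = 0
    cls[ab & ~ao] = 1
    cls[ao & ~ab] = 2
    cls[bo & ~ab & ~ao] = 3
    counts = np.bincount(cls, minlength=5).astype(float)
    triplet._pattern_counts = counts
    return counts


def dataset_pattern_counts(dataset: TripletDataset):
    """Group pattern counts by pair configuration.

    Returns dict config -> (counts (n, 5), list of locus ids)."""
    groups: dict[str, tuple[list[np.ndarray], list[str]]] = {}
    for t in dataset:
        counts, ids = groups.setdefault(t.pair_config, ([], []))
        counts.append(pattern_counts(t))
        ids.append(t.locus_id)
    return {
        cfg: (np.vstack(counts), ids) for cfg, (counts, ids) in groups.items()
    }


def alignment_likelihood_given_tree(
    triplet: TripletAlignment, topology: int, t_inner: float, t_outer: float
) -> float:
    """Log-probability of the alignment given a fixed gene tree (JC69
    pruning, sites with N skipped)."""
    if not 0 <= t_inner <= t_outer:
        raise ValueError("need 0 <= t_inner <= t_outer (nested node times)")
    counts = pattern_counts(triplet)
    logp = _jc_pattern_logprobs(np.array(t_inner), np.array(t_outer))
    return float(counts @ logp[_PERMS[topology]])


# ---------------------------------------------------------------------------
# gene-tree densities
# ---------------------------------------------------------------------------

def _ctmc_generator(params: IMParams):
    """Transient 3-state generator for the two ingroup lineages before
    tau_ir (states: both-invicta, split, both-richteri) and the
    coalescence flux rates out of each state."""
    wa, wb = params.jump_rates
    ca = 2.0 / params.theta_inv
    cb = 2.0 / params.theta_rich
    q = np.array(
        [
            [-(2 * wa + ca), 2 * wa, 0.0],
            [wb, -(wa + wb), wa],
            [0.0, 2 * wb, -(2 * wb + cb)],
        ]
    )
    flux = np.array([ca, 0.0, cb])
    return q, flux


def _ctmc_transients(q: np.ndarray, times: np.ndarray) -> np.ndarray:
    """P(t) = expm(q t) evaluated at each time; shape (n, 3, 3)."""
    vals, vecs = np.linalg.eig(q)
    try:
        vinv = np.linalg.inv(vecs)
        cond_ok = np.linalg.cond(vecs) < 1e10
    except np.linalg.LinAlgError:
        cond_ok = False
    if cond_ok:
        expd = np.exp(np.multiply.outer(times, vals))  # (n, 3)
        p = np.einsum("ij,nj,jk->nik", vecs, expd, vinv)
        return np.real(p)
    from scipy.linalg import expm

    return np.stack([expm(q * t) for t in np.atleast_1d(times)])


_INIT_ROW = {"II": 0, "RI": 1, "RR": 2}


@dataclass(eq=False)
class GeneTreeDensity:
    """Joint density of (topology, t_inner, t_outer) for one pair
    configuration; ``model`` selects complete isolation ("null") or
    isolation with migration ("im")."""

    params: IMParams
    pair_config: str
    model: str

    def __post_init__(self) -> None:
        if self.model not in ("null", "im"):
            raise ValueError("model must be 'null' or 'im'")
        if self.model == "im" and self.params.is_null:
            # continuity: an IM density with M = 0 is valid and must match null
            pass
        if self.model == "null" and not self.params.is_null:
            raise ValueError("null model requires zero migration rates")
        self.params.validate()

    def _phase1_flux(self, t: np.ndarray) -> np.ndarray:
        p = self.params
        t = np.asarray(t, dtype=float)
        if self.model == "null":
            if self.pair_config == "II":
                return (2 / p.theta_inv) * np.exp(-2 * t / p.theta_inv)
            if self.pair_config == "RR":
                return (2 / p.theta_rich) * np.exp(-2 * t / p.theta_rich)
            return np.zeros_like(t)
        q, flux = _ctmc_generator(p)
        pt = _ctmc_transients(q, t)
        return pt[:, _INIT_ROW[self.pair_config], :] @ flux

    def _survival_tau1(self) -> float:
        p = self.params
        if self.model == "null":
            if self.pair_config == "II":
                return float(np.exp(-2 * p.tau_ir / p.theta_inv))
            if self.pair_config == "RR":
                return float(np.exp(-2 * p.tau_ir / p.theta_rich))
            return 1.0
        q, _ = _ctmc_generator(p)
        pt = _ctmc_transients(q, np.array([p.tau_ir]))
        return float(pt[0, _INIT_ROW[self.pair_config], :].sum())

    def pdf(self, topology, t_inner, t_outer) -> np.ndarray:
        p = self.params
        topology = np.asarray(topology)
        t1 = np.asarray(t_inner, dtype=float)
        t0 = np.asarray(t_outer, dtype=float)
        tau1, tau0, thr = p.tau_ir, p.tau_root, p.theta_root
        s1 = self._survival_tau1()
        s2 = s1 * np.exp(-2 * (tau0 - tau1) / p.theta_anc_ir)

        shape = np.broadcast(topology, t1, t0).shape
        t1b = np.broadcast_to(t1, shape).ravel()
        t0b = np.broadcast_to(t0, shape).ravel()
        topob = np.broadcast_to(topology, shape).ravel()
        out = np.zeros(t1b.shape)
        hb = (2 / thr) * np.exp(-2 * (t0b - tau0) / thr)
        m1 = (t1b > 0) & (t1b < tau1) & (topob == TOPO_INGROUP) & (t0b > tau0)
        if m1.any():
            out[m1] = self._phase1_flux(t1b[m1]) * hb[m1]
        m2 = (t1b >= tau1) & (t1b < tau0) & (topob == TOPO_INGROUP) & (t0b > tau0)
        if m2.any():
            out[m2] = (
                s1
                * (2 / p.theta_anc_ir)
                * np.exp(-2 * (t1b[m2] - tau1) / p.theta_anc_ir)
                * hb[m2]
            )
        m3 = (t1b >= tau0) & (t0b > t1b)
        if m3.any():
            out[m3] = (
                s2
                * (2 / thr)
                * np.exp(-6 * (t1b[m3] - tau0) / thr)
                * (2 / thr)
                * np.exp(-2 * (t0b[m3] - t1b[m3]) / thr)
            )
        return out.reshape(shape) if shape else float(out[0])


def gene_tree_density_null(params: IMParams, pair_config: str) -> GeneTreeDensity:
    """Complete-isolation gene-tree density (migration rates must be 0)."""
    return GeneTreeDensity(params=params, pair_config=pair_config, model="null")


def gene_tree_density_im(params: IMParams, pair_config: str) -> GeneTreeDensity:
    """Isolation-with-migration gene-tree density (CTMC before tau_ir)."""
    return GeneTreeDensity(params=params, pair_config=pair_config, model="im")


# ---------------------------------------------------------------------------
# quadrature
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _leggauss(k: int):
    return np.polynomial.legendre.leggauss(k)


def _jacobi_unit(k: int, b: float):
    """Golub-Welsch nodes x in (-1, 1) and weights summing to 1 for the
    normalised Jacobi weight (1+x)^b (alpha = 0).  Stable for very large b,
    unlike forming the unnormalised weights directly."""
    from scipy.linalg import eigh_tridiagonal

    a = np.empty(k)
    a[0] = b / (b + 2.0)
    n = np.arange(1, k)
    a[n] = b * b / ((2 * n + b) * (2 * n + b + 2.0))
    off = np.empty(k - 1)
    off[0] = 4.0 * (1.0 + b) / ((2.0 + b) ** 2 * (3.0 + b))
    n = np.arange(2, k)
    off[n - 1] = (
        4.0 * n * n * (n + b) * (n + b) / ((2 * n + b) ** 2 * ((2 * n + b) ** 2 - 1.0))
    )
    vals, vecs = eigh_tridiagonal(a, np.sqrt(off))
    w = vecs[0] ** 2
    return vals, w / w.sum()


def _exp_nodes(rate: float, upper: float | None, k: int):
    """Nodes/weights for integrating g against the exponential(rate) density
    on (0, upper); weights sum to the interval's probability mass.

    On (0, inf) the integrand's slow scale is the JC69 mutation scale, so
    substitute v = exp(-4t/3): the exponential weight becomes the Beta
    density beta*v^(beta-1) with beta = 3*rate/4, integrated exactly by a
    Gauss-Jacobi rule (two-scale integrands converge at machine precision).
    On a finite interval use Gauss-Legendre in v with the weight evaluated
    explicitly (machine precision while rate*upper is moderate); once the
    weight is so steep that the interval is effectively infinite
    (rate*upper > 30, truncated mass < 1e-13) reuse the Jacobi rule with
    nodes capped at the upper limit.
    """
    beta = 0.75 * rate
    if upper is None or rate * upper > 30.0:
        x, w = _jacobi_unit(k, beta - 1.0)
        t = -0.75 * np.log1p((x - 1.0) / 2.0)
        if upper is not None:
            t = np.minimum(t, upper)
        return t, w
    x, w = _leggauss(k)
    v_min = float(np.exp(-4.0 * upper / 3.0))
    v = v_min + (1.0 - v_min) * (x + 1.0) / 2.0
    t = -0.75 * np.log(v)
    wt = w * (1.0 - v_min) / 2.0 * beta * np.exp((beta - 1.0) * np.log(v))
    return t, wt


def _quadrature_blocks(params: IMParams, pair_config: str, model: str, k: int):
    """Assemble quadrature nodes for one pair configuration.

    Returns a list of blocks (t1, t0, log_weight, topology), each flat
    arrays of equal length; summing exp(log_weight) over all blocks gives
    (approximately, exactly for the null model) 1.
    """
    p = params
    tau1, tau0 = p.tau_ir, p.tau_root
    rate_root = 2.0 / p.theta_root
    v_t, v_w = _exp_nodes(rate_root, None, k)  # t0 = tau0 + v for phases 1-2

    blocks = []
    tiny = 1e-300

    # phase 1: ingroup coalescence before tau1
    if model == "null":
        theta_own = {"II": p.theta_inv, "RR": p.theta_rich}.get(pair_config)
        if theta_own is not None:
            rate1 = 2.0 / theta_own
            t1a, w1a = _exp_nodes(rate1, tau1, k)
            s1 = float(np.exp(-rate1 * tau1))
        else:
            t1a, w1a, s1 = None, None, 1.0
    else:
        q, flux = _ctmc_generator(p)
        x, w = _leggauss(k)
        t1a = tau1 * (x + 1.0) / 2.0
        pt = _ctmc_transients(q, np.concatenate([t1a, [tau1]]))
        row = _INIT_ROW[pair_config]
        f = np.clip(pt[:-1, row, :] @ flux, 0.0, None)
        w1a = w * (tau1 / 2.0) * f
        s1 = float(np.clip(pt[-1, row, :].sum(), 0.0, 1.0))
        if not np.any(w1a > 0):
            t1a = None

    if t1a is not None:
        tt1 = np.repeat(t1a, k)
        tt0 = tau0 + np.tile(v_t, len(t1a))
        ww = np.repeat(w1a, k) * np.tile(v_w, len(t1a))
        blocks.append((tt1, tt0, np.log(np.maximum(ww, tiny)), TOPO_INGROUP))

    # phase 2: coalescence in the ingroup ancestor on (tau1, tau0)
    rate2 = 2.0 / p.theta_anc_ir
    t2, w2 = _exp_nodes(rate2, tau0 - tau1, k)
    s2 = s1 * float(np.exp(-rate2 * (tau0 - tau1)))
    tt1 = np.repeat(tau1 + t2, k)
    tt0 = tau0 + np.tile(v_t, len(t2))
    ww = s1 * np.repeat(w2, k) * np.tile(v_w, len(t2))
    blocks.append((tt1, tt0, np.log(np.maximum(ww, tiny)), TOPO_INGROUP))

    # phase 3: three lineages in the root population
    u1_t, u1_w = _exp_nodes(6.0 / p.theta_root, None, k)
    u2_t, u2_w = _exp_nodes(rate_root, None, k)
    tt1 = tau0 + np.repeat(u1_t, k)
    tt0 = tt1 + np.tile(u2_t, len(u1_t))
    ww = (s2 / 3.0) * np.repeat(u1_w, k) * np.tile(u2_w, len(u1_t))
    logw3 = np.log(np.maximum(ww, tiny))
    for topo in (TOPO_INGROUP, TOPO_A_OUT, TOPO_B_OUT):
        blocks.append((tt1, tt0, logw3, topo))
    return blocks


def _config_locus_logliks(
    counts: np.ndarray, params: IMParams, pair_config: str, model: str, k: int
) -> np.ndarray:
    """Per-locus log-likelihoods for all loci sharing one configuration."""
    blocks = _quadrature_blocks(params, pair_config, model, k)
    logps, logws = [], []
    cached_logp: dict[int, np.ndarray] = {}
    for t1, t0, logw, topo in blocks:
        key = id(t1)
        if key not in cached_logp:
            cached_logp[key] = _jc_pattern_logprobs(t1, t0)
        logps.append(cached_logp[key][:, _PERMS[topo]])
        logws.append(logw)
    logp = np.concatenate(logps, axis=0)  # (n_nodes_total, 5)
    logw = np.concatenate(logws)
    ll = counts @ logp.T + logw  # (n_loci, n_nodes_total)
    m = ll.max(axis=1)
    return m + np.log(np.exp(ll - m[:, None]).sum(axis=1))


def per_locus_loglik(
    dataset: TripletDataset, params: IMParams, model: str, quadrature_points: int = 16
) -> np.ndarray:
    """Log-likelihood per locus, ordered as the dataset."""
    groups = dataset_pattern_counts(dataset)
    order = {t.locus_id: i for i, t in enumerate(dataset)}
    out = np.empty(len(dataset))
    for cfg, (counts, ids) in groups.items():
        ll = _config_locus_logliks(counts, params, cfg, model, quadrature_points)
        if not np.all(np.isfinite(ll)):
            bad = [lid for lid, v in zip(ids, ll) if not np.isfinite(v)]
            raise FloatingPointError(f"non-finite likelihood at loci {bad[:5]}")
        for lid, v in zip(ids, ll):
            out[order[lid]] = v
    return out


def total_loglik(
    dataset: TripletDataset,
    params: IMParams,
    model: str = "null",
    config: IMFitConfig | None = None,
) -> float:
    """Total log-likelihood of the dataset (sum over independent loci)."""
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    k = (config or IMFitConfig()).quadrature_points
    return float(per_locus_loglik(dataset, params, model, k).sum())


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_LOG_BOUNDS = {
    "theta": (np.log(1e-5), np.log(0.5)),
    "tau1": (np.log(1e-6), np.log(0.1)),
    "dtau": (np.log(1e-6), np.log(0.2)),
    "mig": (np.log(1e-8), np.log(20.0)),
}


def _x_to_params(x: np.ndarray, model: str) -> IMParams:
    th_i, th_r, th_a, th_o, tau1, dtau = np.exp(x[:6])
    mig_a = mig_b = 0.0
    if model == "im":
        mig_a, mig_b = np.exp(x[6:8])
    return IMParams(
        tau_ir=tau1,
        tau_root=tau1 + dtau,
        theta_inv=th_i,
        theta_rich=th_r,
        theta_anc_ir=th_a,
        theta_root=th_o,
        mig_inv_to_rich=mig_a,
        mig_rich_to_inv=mig_b,
    )


def _params_to_x(p: IMParams, model: str) -> np.ndarray:
    x = np.log(
        [p.theta_inv, p.theta_rich, p.theta_anc_ir, p.theta_root, p.tau_ir,
         max(p.tau_root - p.tau_ir, 1e-6)]
    )
    if model == "im":
        x = np.concatenate(
            [x, np.log([max(p.mig_inv_to_rich, 1e-8), max(p.mig_rich_to_inv, 1e-8)])]
        )
    return x


def _jc_distance(p_mismatch: float) -> float:
    p = min(p_mismatch, 0.70)
    return float(-0.75 * np.log(max(1.0 - 4.0 * p / 3.0, 1e-6)))


def _moment_init(groups) -> IMParams:
    """Method-of-moments starting point from JC distances between sequence
    pairs, averaged per configuration class."""
    def mean_dist(cfg, classes):
        if cfg not in groups:
            return None
        counts, _ = groups[cfg]
        tot = counts.sum()
        if tot == 0:
            return None
        return _jc_distance(counts[:, classes].sum() / tot)

    th_i = mean_dist("II", [2, 3, 4]) or 0.004
    th_r = mean_dist("RR", [2, 3, 4]) or th_i
    theta_bar = 0.5 * (th_i + th_r)
    d_ri = mean_dist("RI", [2, 3, 4])
    tau1 = max((d_ri - theta_bar) / 2.0, theta_bar / 4.0) if d_ri else theta_bar / 2.0
    d_out = np.mean(
        [
            d
            for d in (
                mean_dist(cfg, [1, 3, 4]) for cfg in ("II", "RR", "RI")
            )
            if d is not None
        ]
    )
    tau0 = max(d_out / 2.0 * 0.8, tau1 * 1.5)
    return IMParams(
        tau_ir=min(tau1, 0.9 * tau0),
        tau_root=tau0,
        theta_inv=th_i,
        theta_rich=th_r,
        theta_anc_ir=theta_bar,
        theta_root=max(d_out / 4.0, theta_bar),
        mig_inv_to_rich=0.0,
        mig_rich_to_inv=0.0,
    )


def fit_model(
    dataset: TripletDataset,
    model: str = "null",
    config: IMFitConfig | None = None,
    init_params: IMParams | None = None,
) -> FitResult:
    """Maximise the total log-likelihood over log-transformed parameters
    from multiple starting points; returns the best fit and all starts."""
    if model not in ("null", "im"):
        raise ValueError("model must be 'null' or 'im'")
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    config = config or IMFitConfig()
    k = config.quadrature_points
    groups = dataset_pattern_counts(dataset)
    rng = np.random.default_rng(config.seed)

    def negloglik(x: np.ndarray) -> float:
        try:
            p = _x_to_params(x, model)
        except ValueError:
            return 1e12
        total = 0.0
        for cfg, (counts, _) in groups.items():
            ll = _config_locus_logliks(counts, p, cfg, model, k)
            if not np.all(np.isfinite(ll)):
                return 1e12
            total += ll.sum()
        return -total

    base = init_params or _moment_init(groups)
    n_par = 8 if model == "im" else 6
    bounds = (
        [_LOG_BOUNDS["theta"]] * 4
        + [_LOG_BOUNDS["tau1"], _LOG_BOUNDS["dtau"]]
        + ([_LOG_BOUNDS["mig"]] * 2 if model == "im" else [])
    )

    starts_x = []
    x0 = _params_to_x(base, model)
    starts_x.append(x0)
    if model == "im":
        # the log-migration gradient vanishes at the M ~ 0 boundary, so a
        # migration-positive start is always included
        x_mig = x0.copy()
        x_mig[6:8] = np.log(0.5)
        starts_x.append(x_mig)
    for _ in range(config.n_starts - 1):
        jitter = rng.normal(0.0, 0.3, n_par)
        starts_x.append(x0 + jitter)

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    records, best = [], None
    for x_start in starts_x:
        x_start = np.clip(x_start, lo, hi)
        res = minimize(
            negloglik,
            x_start,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": config.max_iter, "ftol": config.optimizer_tol},
        )
        rec = {
            "x0": x_start.copy(),
            "loglik": -float(res.fun),
            "converged": bool(res.success),
            "params": _x_to_params(res.x, model),
        }
        records.append(rec)
        if best is None or rec["loglik"] > best["loglik"]:
            best = rec
    if best is None or not np.isfinite(best["loglik"]):
        raise RuntimeError(f"no start converged for model {model!r}: {records}")
    return FitResult(
        model=model,
        params=best["params"],
        loglik=best["loglik"],
        starts=records,
        converged=any(r["converged"] for r in records),
    )


def likelihood_ratio_test(
    lnl_null: float, lnl_im: float, df: int = 2, tol: float = 1e-3
) -> tuple[float, float]:
    """Delta log-likelihood and chi-square p-value of the nested
    comparison.  df defaults to 2 (two directional migration rates); with
    migration constrained non-negative the chi-square reference is
    conservative.  A negative delta beyond tolerance signals optimizer
    failure and raises."""
    delta = lnl_im - lnl_null
    if delta < -tol:
        raise ValueError(
            f"lnL(IM) < lnL(null) by {-delta:.4g}: optimizer failure on the IM fit"
        )
    delta = max(delta, 0.0)
    p = float(chi2.sf(2.0 * delta, df)) if delta > 0 else 1.0
    return delta, p


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class IsolationMigrationModel:
    """Triplet-alignment likelihood model; fit() returns :class:`IMResults`."""

    def __init__(self, dataset: TripletDataset, config: IMFitConfig | None = None):
        self.dataset = dataset
        self.config = config or IMFitConfig()

    @classmethod
    def from_file(cls, path, config: IMFitConfig | None = None):
        from .io_formats import read_triplets

        return cls(read_triplets(path), config=config)

    def fit(self, model: str = "null", init_params: IMParams | None = None):
        res = fit_model(self.dataset, model=model, config=self.config,
                        init_params=init_params)
        return IMResults(self, res)

    def fit_both(self):
        """Fit isolation and isolation-with-migration; the IM fit is
        warm-started from the isolation MLE so the nesting inequality holds
        numerically.  Returns (null_results, im_results, (delta, p))."""
        res_null = self.fit("null")
        res_im = self.fit("im", init_params=replace(
            res_null.result.params, mig_inv_to_rich=1e-6, mig_rich_to_inv=1e-6
        ))
        lrt = likelihood_ratio_test(res_null.loglik, res_im.loglik)
        return res_null, res_im, lrt


class IMResults:
    def __init__(self, model_obj: IsolationMigrationModel, result: FitResult):
        self.model_obj = model_obj
        self.result = result

    @property
    def loglik(self) -> float:
        return self.result.loglik

    @property
    def params(self) -> IMParams:
        return self.result.params

    def lrt(self, null_results: "IMResults", df: int = 2) -> tuple[float, float]:
        return likelihood_ratio_test(null_results.loglik, self.loglik, df=df)

    def summary(self) -> str:
        p = self.params
        lines = [
            f"Model: {'isolation with migration' if self.result.model == 'im' else 'complete isolation'}",
            f"log-likelihood: {self.loglik:.6f}",
            f"n loci: {len(self.model_obj.dataset)}",
            "",
            f"{'parameter':<16}{'estimate':>14}",
            f"{'tau_ir':<16}{p.tau_ir:>14.6g}",
            f"{'tau_root':<16}{p.tau_root:>14.6g}",
            f"{'theta_invicta':<16}{p.theta_inv:>14.6g}",
            f"{'theta_richteri':<16}{p.theta_rich:>14.6g}",
            f"{'theta_anc_ir':<16}{p.theta_anc_ir:>14.6g}",
            f"{'theta_root':<16}{p.theta_root:>14.6g}",
        ]
        if self.result.model == "im":
            lines += [
                f"{'M_inv->rich':<16}{p.mig_inv_to_rich:>14.6g}",
                f"{'M_rich->inv':<16}{p.mig_rich_to_inv:>14.6g}",
            ]
        lines.append("")
        lines.append(
            "starts: "
            + ", ".join(f"{r['loglik']:.4f}" for r in self.result.starts)
        )
        return "\n".join(lines)
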