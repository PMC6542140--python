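"""Coalescent simulators for the two halves of the analysis.

Genotype matrices are simulated under the four-population fire-ant
scenario (two native clusters, a founder bottleneck, the contemporary
introduced population) with msprime, producing one biallelic SNP per locus
by placing a single mutation on the genealogy with probability proportional
to branch length — the scheme used by SNP-mode ABC engines, matching
observed one-SNP-per-record RAD catalogs.  Because exactly one mutation is
placed per tree, no mutation-rate parameter enters: genotype patterns
depend on tree shape alone.

Triplet alignments (two ingroup sequences + outgroup) are simulated under
a three-species coalescent, with or without migration between the two
ingroup species, and sequences evolved by JC69.  Times and population
sizes are scaled in expected substitutions per site (tau, theta).

Haplodiploidy is handled at interpretation time (theta = 3*mu*Ne), not in
the simulator: sizes here are effective diploid-equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np

from .io_formats import GenotypeMatrix, Locus, TripletAlignment, TripletDataset

POP_NAMES = ("N1", "N2", "I")
_BASES = "ACGT"


@dataclass
class InvictaScenarioParams:
    """The four-population demographic scenario.

    Sizes are effective diploid-equivalent individuals; times are
    generations before sampling.  Backward in time, the introduced deme has
    size ``n_introduced`` on (0, T_I - T_B), size ``n_founder`` during the
    bottleneck (T_I - T_B, T_I), and merges into the Herradura-like native
    cluster at T_I; the second native cluster merges into the first at T_D.
    """

    n_native1: float
    n_native2: float
    n_founder: float
    n_introduced: float
    t_divergence: float  # T_D
    t_introduction: float  # T_I
    t_bottleneck: float  # T_B (duration)

    def validate(self) -> None:
        for name in ("n_native1", "n_native2", "n_founder", "n_introduced"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 <= self.t_bottleneck <= self.t_introduction <= self.t_divergence):
            raise ValueError("need 0 <= T_B <= T_I <= T_D")

    def __post_init__(self) -> None:
        self.validate()

    def as_dict(self) -> dict[str, float]:
        return {
            "N_N1": self.n_native1,
            "N_N2": self.n_native2,
            "N_F": self.n_founder,
            "N_I": self.n_introduced,
            "T_D": self.t_divergence,
            "T_I": self.t_introduction,
            "T_B": self.t_bottleneck,
        }

    @classmethod
    def from_dict(cls, d) -> "InvictaScenarioParams":
        return cls(
            n_native1=d["N_N1"], n_native2=d["N_N2"], n_founder=d["N_F"],
            n_introduced=d["N_I"], t_divergence=d["T_D"],
            t_introduction=d["T_I"], t_bottleneck=d["T_B"],
        )


@dataclass
class SampleSpec:
    """How many diploid samples per population and how many loci."""

    samples: dict[str, int] = field(
        default_factory=lambda: {"N1": 14, "N2": 13, "I": 13}
    )
    n_loci: int = 1500
    locus_length: int = 96

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.samples.values()) or self.n_loci < 0:
            raise ValueError("counts must be >= 0")
        if self.locus_length < 1:
            raise ValueError("locus_length must be >= 1")


@dataclass
class IMParams:
    """Three-species coalescent parameters in mutational units.

    ``tau_ir`` / ``tau_root`` are the ingroup and root divergence times in
    expected substitutions per site; thetas are per-site scaled diversities
    (4*mu*Ne on the diploid scale).  ``mig_inv_to_rich`` is the scaled
    migration parameter M = N*m such that, backward in time, a lineage
    currently in S. invicta relocates to S. richteri at rate
    4*M/theta_inv per unit mutational time (and symmetrically for
    ``mig_rich_to_inv``).  Both zero gives the complete-isolation model.
    """

    tau_ir: float
    tau_root: float
    theta_inv: float
    theta_rich: float
    theta_anc_ir: float
    theta_root: float
    mig_inv_to_rich: float = 0.0
    mig_rich_to_inv: float = 0.0

    def validate(self) -> None:
        if not 0 < self.tau_ir < self.tau_root:
            raise ValueError("need 0 < tau_ir < tau_root")
        for name in ("theta_inv", "theta_rich", "theta_anc_ir", "theta_root"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.mig_inv_to_rich < 0 or self.mig_rich_to_inv < 0:
            raise ValueError("migration rates must be >= 0")

    def __post_init__(self) -> None:
        self.validate()

    @property
    def is_null(self) -> bool:
        return self.mig_inv_to_rich == 0.0 and self.mig_rich_to_inv == 0.0

    @property
    def jump_rates(self) -> tuple[float, float]:
        """Backward relocation rates (invicta->richteri, richteri->invicta)
        per unit mutational time."""
        return (
            4.0 * self.mig_inv_to_rich / self.theta_inv,
            4.0 * self.mig_rich_to_inv / self.theta_rich,
        )


#: Table-1-like point estimates of the complete-isolation fit, used as the
#: default parameter set for synthetic triplet data.
TABLE1_PARAMS = IMParams(
    tau_ir=0.000646,
    tau_root=0.008369,
    theta_inv=0.004062,
    theta_rich=0.003596,
    theta_anc_ir=0.002293,
    theta_root=0.026874,
)


# ---------------------------------------------------------------------------
# four-population genotype simulation
# ---------------------------------------------------------------------------

def build_demography(params: InvictaScenarioParams) -> msprime.Demography:
    params.validate()
    dem = msprime.Demography()
    dem.add_population(name="N1", initial_size=params.n_native1)
    dem.add_population(name="N2", initial_size=params.n_native2)
    dem.add_population(name="I", initial_size=params.n_introduced)
    if params.t_bottleneck > 0 and params.n_founder != params.n_introduced:
        dem.add_population_parameters_change(
            time=params.t_introduction - params.t_bottleneck,
            population="I",
            initial_size=params.n_founder,
        )
    dem.add_mass_migration(
        time=params.t_introduction, source="I", dest="N1", proportion=1.0
    )
    dem.add_mass_migration(
        time=params.t_divergence, source="N2", dest="N1", proportion=1.0
    )
    dem.sort_events()
    return dem


def _place_snp(ts, u: float, n_sample_nodes: int) -> np.ndarray:
    """Place one mutation uniformly on total branch length of a single-tree
    sequence; return the derived sample nodes.  ``u`` is a uniform(0,1)
    draw.  Any non-root branch subtends a proper subset of the samples, so
    the pooled sample is always polymorphic.

    Works on the raw edge arrays (sample nodes are 0..n-1, parents have
    higher ids than children) to keep per-locus overhead low.
    """
    child = ts.edges_child
    parent = ts.edges_parent
    blen = ts.nodes_time[parent] - ts.nodes_time[child]
    cum = np.cumsum(blen)
    k = int(np.searchsorted(cum, u * cum[-1], side="right"))
    node = int(child[min(k, len(blen) - 1)])
    if node < n_sample_nodes:
        return np.array([node], dtype=np.int64)
    order = np.argsort(parent, kind="stable")
    sp, sc = parent[order], child[order]
    stack, leaves = [node], []
    while stack:
        v = stack.pop()
        if v < n_sample_nodes:
            leaves.append(v)
            continue
        lo = np.searchsorted(sp, v, side="left")
        hi = np.searchsorted(sp, v, side="right")
        stack.extend(sc[lo:hi].tolist())
    return np.array(leaves, dtype=np.int64)


def simulate_invicta_scenario(
    params: InvictaScenarioParams,
    spec: SampleSpec,
    seed: int,
    engine: str = "hudson",
) -> GenotypeMatrix:
    """Simulate one biallelic SNP per locus under the scenario.

    Loci are independent (one contig each); the same seed and engine
    reproduce the same matrix bit-for-bit.  ``engine="hudson"`` runs
    msprime; ``engine="fast"`` runs an equivalent compiled Kingman sampler
    specialised to this three-deme piecewise history (used for large ABC
    reference tables; the two engines are cross-validated distributionally
    in the test suite).
    """
    params.validate()
    if engine not in ("hudson", "fast"):
        raise ValueError("engine must be 'hudson' or 'fast'")
    sample_counts = {p: spec.samples.get(p, 0) for p in POP_NAMES}
    n_ind = sum(sample_counts.values())
    pop_labels = [p for p in POP_NAMES for _ in range(sample_counts[p])]

    if engine == "fast":
        calls = _simulate_calls_fast(params, sample_counts, spec.n_loci, seed)
    else:
        dem = build_demography(params)
        ss = np.random.SeedSequence(seed)
        ms_seed = int(np.random.default_rng(ss.spawn(1)[0]).integers(1, 2**31 - 1))
        rng = np.random.default_rng(ss)
        reps = msprime.sim_ancestry(
            samples=sample_counts,
            demography=dem,
            ploidy=2,
            num_replicates=spec.n_loci,
            random_seed=ms_seed,
        )
        calls = np.zeros((n_ind, spec.n_loci), dtype=np.int8)
        us = rng.random(spec.n_loci)
        for j, ts in enumerate(reps):
            derived_nodes = _place_snp(ts, us[j], 2 * n_ind)
            # sample node i belongs to diploid individual i // 2
            calls[:, j] = np.bincount(derived_nodes // 2, minlength=n_ind)
    loci = [Locus(f"locus{j:06d}", 1, "A", "T") for j in range(spec.n_loci)]
    return GenotypeMatrix(
        sample_ids=[f"{p}_{i:03d}" for p in POP_NAMES for i in range(sample_counts[p])],
        pop_labels=pop_labels,
        loci=loci,
        calls=calls,
    )


def _simulate_calls_fast(
    params: InvictaScenarioParams,
    sample_counts: dict[str, int],
    n_loci: int,
    seed: int,
) -> np.ndarray:
    """Compiled three-deme piecewise Kingman sampler with the same
    one-mutation-per-locus SNP scheme as the msprime path."""
    from ._fast_coalescent import simulate_scenario_calls

    t_ib = params.t_introduction - params.t_bottleneck
    return simulate_scenario_calls(
        int(sample_counts.get("N1", 0)),
        int(sample_counts.get("N2", 0)),
        int(sample_counts.get("I", 0)),
        float(params.n_native1),
        float(params.n_native2),
        float(params.n_introduced),
        float(params.n_founder),
        float(t_ib),
        float(params.t_introduction),
        float(params.t_divergence),
        int(n_loci),
        int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# three-species triplet genealogies
# ---------------------------------------------------------------------------

_INIT_STATE = {"II": 0, "RI": 1, "RR": 2}  # 0 = both invicta, 1 = split, 2 = both richteri

#: topology codes: which pair forms the cherry
TOPO_INGROUP, TOPO_A_OUT, TOPO_B_OUT = 0, 1, 2


def prob_ingroup_coalescence_before_split(params: IMParams, pair_config: str) -> float:
    """Closed form (isolation model only): probability that a same-species
    pair coalesces before tau_ir."""
    if not params.is_null:
        raise ValueError("closed form applies to the isolation model only")
    if pair_config == "II":
        return 1.0 - float(np.exp(-2.0 * params.tau_ir / params.theta_inv))
    if pair_config == "RR":
        return 1.0 - float(np.exp(-2.0 * params.tau_ir / params.theta_rich))
    return 0.0


def simulate_triplet_genealogy(
    params: IMParams,
    pair_config: str,
    rng: np.random.Generator,
    size: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw gene trees from the exact three-species model density.

    Returns ``(topology, t_inner, t_outer)`` arrays: the cherry topology
    code (0: ingroup pair; 1: ingroup-a with outgroup; 2: ingroup-b with
    outgroup), the cherry coalescence time and the root coalescence time,
    all in mutational units.
    """
    params.validate()
    if pair_config not in _INIT_STATE:
        raise ValueError(f"pair_config must be one of {tuple(_INIT_STATE)}")
    tau1, tau0 = params.tau_ir, params.tau_root
    t1 = np.full(size, np.nan)

    wa, wb = params.jump_rates
    if wa == 0.0 and wb == 0.0:
        if pair_config == "II":
            e = rng.exponential(params.theta_inv / 2.0, size)
            t1 = np.where(e < tau1, e, np.nan)
        elif pair_config == "RR":
            e = rng.exponential(params.theta_rich / 2.0, size)
            t1 = np.where(e < tau1, e, np.nan)
    else:
        t1 = _gillespie_two_lineages(params, pair_config, rng, size)

    # ancestral ingroup population (tau1, tau0)
    open_ = np.isnan(t1)
    n_open = int(open_.sum())
    if n_open:
        e2 = tau1 + rng.exponential(params.theta_anc_ir / 2.0, n_open)
        t1_open = np.where(e2 < tau0, e2, np.nan)
        t1[open_] = t1_open

    topo = np.zeros(size, dtype=np.int64)
    t0 = np.empty(size)
    closed = ~np.isnan(t1)
    # merged ingroup lineage meets the outgroup lineage in the root population
    t0[closed] = tau0 + rng.exponential(params.theta_root / 2.0, int(closed.sum()))
    # three lineages enter the root population
    n3 = int((~closed).sum())
    if n3:
        u1 = rng.exponential(params.theta_root / 6.0, n3)
        pair = rng.integers(0, 3, n3)
        u2 = rng.exponential(params.theta_root / 2.0, n3)
        t1[~closed] = tau0 + u1
        t0[~closed] = tau0 + u1 + u2
        topo[~closed] = pair
    return topo, t1, t0


def _gillespie_two_lineages(
    params: IMParams, pair_config: str, rng: np.random.Generator, size: int
) -> np.ndarray:
    """Event-driven simulation of the two ingroup lineages before tau_ir
    under migration; returns coalescence times (NaN if none by tau_ir)."""
    wa, wb = params.jump_rates
    c_inv = 2.0 / params.theta_inv
    c_rich = 2.0 / params.theta_rich
    tau1 = params.tau_ir
    state = np.full(size, _INIT_STATE[pair_config], dtype=np.int64)
    t = np.zeros(size)
    t1 = np.full(size, np.nan)
    active = np.ones(size, dtype=bool)
    while active.any():
        rates = np.where(
            state == 0, 2 * wa + c_inv, np.where(state == 1, wa + wb, 2 * wb + c_rich)
        )
        with np.errstate(divide="ignore"):
            dt = rng.exponential(1.0, size) / rates  # inf where rate 0
        t = t + np.where(active, dt, 0.0)
        active &= t < tau1
        if not active.any():
            break
        u = rng.random(size)
        s0 = active & (state == 0)
        s1 = active & (state == 1)
        s2 = active & (state == 2)
        coal = (s0 & (u < c_inv / (2 * wa + c_inv))) | (
            s2 & (u < c_rich / (2 * wb + c_rich))
        )
        t1[coal] = t[coal]
        active &= ~coal
        move_out0 = s0 & ~coal & active
        move_out2 = s2 & ~coal & active
        to_inv = s1 & (u < (wb / (wa + wb) if (wa + wb) > 0 else 0.0))
        to_rich = s1 & ~to_inv
        state[move_out0 | move_out2] = 1
        state[to_inv & active] = 0
        state[to_rich & active] = 2
    return t1


# ---------------------------------------------------------------------------
# sequence evolution (JC69)
# ---------------------------------------------------------------------------

def _jc_evolve(parent: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve integer-coded bases along a branch of length t (expected
    substitutions per site) under JC69."""
    p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
    mask = rng.random(parent.shape) < p_change
    shift = rng.integers(1, 4, parent.shape)
    return np.where(mask, (parent + shift) % 4, parent)


def simulate_triplets(
    params: IMParams,
    n_loci: int,
    locus_length: int = 96,
    config_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    seed: int = 0,
) -> TripletDataset:
    """Simulate a triplet dataset: per locus, a pair configuration drawn
    from ``config_mix`` (II, RR, RI), a gene tree from the model and JC69
    sequences.  Deterministic under ``seed``."""
    if n_loci < 0:
        raise ValueError("n_loci must be >= 0")
    mix = np.asarray(config_mix, dtype=float)
    if mix.size != 3 or abs(mix.sum() - 1.0) > 1e-9 or (mix < 0).any():
        raise ValueError("config_mix must be 3 non-negative proportions summing to 1")
    rng = np.random.default_rng(seed)
    configs = rng.choice(np.array(["II", "RR", "RI"]), size=n_loci, p=mix)
    triplets: list[TripletAlignment] = []
    for j in range(n_loci):
        cfg = str(configs[j])
        topo, t1, t0 = simulate_triplet_genealogy(params, cfg, rng, size=1)
        topo, t1, t0 = int(topo[0]), float(t1[0]), float(t0[0])
        root = rng.integers(0, 4, locus_length)
        inner = _jc_evolve(root, t0 - t1, rng)
        x = _jc_evolve(inner, t1, rng)
        y = _jc_evolve(inner, t1, rng)
        z = _jc_evolve(root, t0, rng)
        if topo == TOPO_INGROUP:
            a, b, out = x, y, z
        elif topo == TOPO_A_OUT:
            a, out, b = x, y, z
        else:
            b, out, a = x, y, z
        to_str = lambda arr: "".join(_BASES[int(v)] for v in arr)
        triplets.append(
            TripletAlignment(
                locus_id=f"L{j:05d}",
                seq_a=to_str(a),
                seq_b=to_str(b),
                seq_out=to_str(out),
                pair_config=cfg,
            )
        )
    return TripletDataset(triplets=triplets, spacing_ok=True)
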