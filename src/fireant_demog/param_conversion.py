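"""Convert scaled coalescent estimates into natural units.

tau (expected substitutions per site since a split) divides by the per-site
per-generation mutation rate to give generations; theta converts to an
effective size via theta = 4*mu*Ne for diploids and theta = 3*mu*Ne for
haplodiploids (haploid males carry one genome copy, so a population of Nf
females and Nm males holds 2Nf + Nm copies rather than 2N).  Effective
sizes of breeding groups follow Ne = 4*Nf*Nm/(Nf + Nm) (diploid) and the
standard haplodiploid form Ne = 9*Nf*Nm/(2*Nf + 4*Nm); with single mating
(Nm = Nf) the latter reduces to Ne = 1.5*Nf, so a founder effective size
converts to a count of unrelated singly-mated queens as ceil(Ne / 1.5).

Confidence intervals are propagated by interval arithmetic: an upper bound
on a ratio combines the numerator's upper bound with the denominator's
lower bound, and vice versa.  Display rounding defaults to 2 significant
figures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

#: default generation time (years) for fire-ant colonies; the plausible
#: range reflects colony developmental-stage estimates
DEFAULT_GENERATION_YEARS = 6.0


@dataclass
class Interval:
    """A point estimate with a (low, high) interval."""

    point: float
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        if self.low is None:
            self.low = self.point
        if self.high is None:
            self.high = self.point
        if not self.low <= self.point <= self.high:
            raise ValueError("interval requires low <= point <= high")


@dataclass
class MutationRate:
    point: float = 3.4e-9
    ci_low: float = 2.2e-9
    ci_high: float = 4.9e-9

    def __post_init__(self) -> None:
        if not 0 < self.ci_low <= self.point <= self.ci_high:
            raise ValueError("require 0 < ci_low <= point <= ci_high")


@dataclass
class GenerationTime:
    years: float = DEFAULT_GENERATION_YEARS
    plausible_range: tuple[float, float] = (3.0, 6.0)

    def __post_init__(self) -> None:
        if self.years <= 0:
            raise ValueError("generation time must be > 0")


@dataclass
class BreedingNumbers:
    n_females: float
    n_males: float
    mating_system: str = "single"

    def __post_init__(self) -> None:
        if self.n_females < 0 or self.n_males < 0:
            raise ValueError("breeding numbers must be >= 0")
        if self.mating_system not in ("single", "multiple"):
            raise ValueError("mating_system must be 'single' or 'multiple'")


def round_sig(x: float, sig_figs: int = 2) -> float:
    """Round to significant figures; 0 stays 0."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig_figs - 1))


def _round_interval(iv: Interval, sig_figs: int | None) -> Interval:
    if sig_figs is None:
        return iv
    return Interval(
        point=round_sig(iv.point, sig_figs),
        low=round_sig(iv.low, sig_figs),
        high=round_sig(iv.high, sig_figs),
    )


def tau_to_generations(
    tau: Interval, mu: MutationRate | None = None, sig_figs: int | None = 2
) -> Interval:
    """Generations since a split: tau / mu, intervals propagated as
    (tau_low/mu_high, tau_high/mu_low)."""
    mu = mu or MutationRate()
    if tau.point <= 0 or tau.low <= 0:
        raise ValueError("tau must be > 0")
    return _round_interval(
        Interval(tau.point / mu.point, tau.low / mu.ci_high, tau.high / mu.ci_low),
        sig_figs,
    )


_PLOIDY_FACTOR = {"diploid": 4.0, "haplodiploid": 3.0}


def theta_to_ne(
    theta: Interval,
    mu: MutationRate | None = None,
    ploidy: str = "haplodiploid",
    sig_figs: int | None = 2,
) -> Interval:
    """Effective size: theta/(4*mu) for diploids, theta/(3*mu) for
    haplodiploids."""
    mu = mu or MutationRate()
    if ploidy not in _PLOIDY_FACTOR:
        raise ValueError(f"ploidy must be one of {sorted(_PLOIDY_FACTOR)}")
    if theta.point <= 0 or theta.low <= 0:
        raise ValueError("theta must be > 0")
    f = _PLOIDY_FACTOR[ploidy]
    return _round_interval(
        Interval(
            theta.point / (f * mu.point),
            theta.low / (f * mu.ci_high),
            theta.high / (f * mu.ci_low),
        ),
        sig_figs,
    )


def ne_to_theta(ne: float, mu: MutationRate | None = None,
                ploidy: str = "haplodiploid") -> float:
    """Inverse of :func:`theta_to_ne` (exact, unrounded)."""
    mu = mu or MutationRate()
    return _PLOIDY_FACTOR[ploidy] * mu.point * ne


def effective_size_from_breeders(breeders: BreedingNumbers,
                                 ploidy: str = "haplodiploid") -> float:
    """Ne from breeding female/male counts."""
    nf, nm = breeders.n_females, breeders.n_males
    if nf + nm == 0:
        raise ValueError("at least one breeder required")
    if ploidy == "diploid":
        return 4.0 * nf * nm / (nf + nm)
    if ploidy == "haplodiploid":
        # Ne = 9 Nf Nm / (2 Nf + 4 Nm): reduces to 1.5 Nf at Nm = Nf,
        # the relation behind the singly-mated queen-count conversion
        return 9.0 * nf * nm / (2.0 * nf + 4.0 * nm)
    raise ValueError(f"ploidy must be one of {sorted(_PLOIDY_FACTOR)}")


def _ceil_queens(ne: float) -> int:
    if ne <= 0:
        raise ValueError("effective size must be > 0")
    return max(1, math.ceil(ne / 1.5 - 1e-9))


def founder_ne_to_queens(ne: Interval) -> Interval:
    """Unrelated singly-mated queens behind a founder effective size:
    ceil(Ne/1.5), exact when Ne/1.5 is integral."""
    return Interval(
        point=_ceil_queens(ne.point),
        low=_ceil_queens(ne.low),
        high=_ceil_queens(ne.high),
    )


def generations_to_years(
    generations: Interval,
    gen_time: GenerationTime | None = None,
    sig_figs: int | None = 2,
) -> Interval:
    """Years = generations x generation time."""
    gen_time = gen_time or GenerationTime()
    if generations.point <= 0:
        raise ValueError("generations must be > 0")
    return _round_interval(
        Interval(
            generations.point * gen_time.years,
            generations.low * gen_time.years,
            generations.high * gen_time.years,
        ),
        sig_figs,
    )


#: the six scaled estimates of the complete-isolation fit (point, low, high):
#: two split times and four population diversities.
TABLE1_ESTIMATES = {
    "tau_ingroup_split": Interval(0.000646, 0.00052, 0.00077),
    "tau_root_split": Interval(0.008369, 0.00789, 0.00884),
    "theta_anc_ingroup": Interval(0.002293, 0.00211, 0.00247),
    "theta_root": Interval(0.026874, 0.02591, 0.02783),
    "theta_richteri": Interval(0.003596, 0.00309, 0.00409),
    "theta_invicta": Interval(0.004062, 0.00343, 0.00469),
}


def table1_report(
    estimates: dict[str, Interval] | None = None,
    mu: MutationRate | None = None,
    gen_time: GenerationTime | None = None,
    sig_figs: int | None = 2,
) -> pd.DataFrame:
    """Full conversion table: each tau yields generations and years; each
    theta yields a haplodiploid effective size and the equivalent count of
    breeding females (Ne/1.5, singly-mated).  Six inputs -> twelve derived
    rows, each with propagated interval bounds."""
    estimates = estimates or TABLE1_ESTIMATES
    mu = mu or MutationRate()
    gen_time = gen_time or GenerationTime()
    rows = []

    def add(name, kind, iv: Interval):
        rows.append(
            {"name": name, "kind": kind, "point": iv.point, "low": iv.low,
             "high": iv.high}
        )

    for name, iv in estimates.items():
        if name.startswith("tau"):
            gens = tau_to_generations(iv, mu, sig_figs=None)
            add(f"{name}_generations", "generations", _round_interval(gens, sig_figs))
            add(
                f"{name}_years",
                "years",
                generations_to_years(gens, gen_time, sig_figs=sig_figs),
            )
        elif name.startswith("theta"):
            ne = theta_to_ne(iv, mu, "haplodiploid", sig_figs=None)
            add(f"{name}_ne", "effective_size", _round_interval(ne, sig_figs))
            add(
                f"{name}_breeding_females",
                "breeding_females",
                _round_interval(
                    Interval(ne.point / 1.5, ne.low / 1.5, ne.high / 1.5), sig_figs
                ),
            )
        else:
            raise ValueError(f"estimate {name!r}: name must start with tau/theta")
    return pd.DataFrame(rows, columns=["name", "kind", "point", "low", "high"])
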