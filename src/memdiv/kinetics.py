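"""Colony growth laws and heterogeneous FtsZ-structured population dynamics.

Forward models for bacterial proliferation kinetics:

* delayed exponential growth ``N(t) = N0*exp(G*(t - t0))`` for cell counts
  in the log phase, with apparent inoculum ``N0*exp(-G*t0)``;
* delayed logistic optical-density curves with a stationary plateau;
* dose-response maps for elastoactive additives — linear inhibition for
  membrane stiffeners and Monod saturation for softeners;
* the quadratic rigidity scaling ``G_eff = A*(kappa_crit - kappa)**beta``
  tying colony rates to single-cell membrane mechanics;
* the lag-time/division-success relation ``t0(alpha)``;
* a linear ODE simulator for populations structured into normal, filamentous
  and dead subpopulations with distinct FtsZ content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .constriction import MembraneParams, dispersion

__all__ = [
    "GrowthParams",
    "DoseResponse",
    "ScalingLaw",
    "Subpopulation",
    "StructuredPopulation",
    "delayed_exponential",
    "apparent_inoculum",
    "doubling_time",
    "logistic_od",
    "monod_rate",
    "linear_inhibition",
    "effective_rate_from_rigidity",
    "lag_from_alpha",
    "simulate_structured",
]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class GrowthParams:
    """Kinetic parameters of a single growth curve."""

    N0: float = 100.0          # initial count [cells]
    G: float = 0.22            # specific growth rate [1/h]
    t0: float = 0.0            # lag (induction) time [h]
    Q0: float = 0.02           # initial biomass/OD [OD units]
    Q_inf: float = 1.0         # plateau biomass/OD [OD units]

    def __post_init__(self) -> None:
        if self.N0 <= 0:
            raise ValueError("N0 must be positive")
        if self.G < 0:
            raise ValueError("G must be non-negative")
        if self.t0 < 0:
            raise ValueError("t0 must be non-negative")
        if not self.Q_inf >= self.Q0 > 0:
            raise ValueError("require Q_inf >= Q0 > 0")

    @property
    def tau_p(self) -> float:
        """Doubling time ln2/G [h]."""
        return doubling_time(self.G)


@dataclass(frozen=True)
class DoseResponse:
    """Dose-response parameters for a growth-modifying additive."""

    c_inh: float = 0.22        # complete-inhibition concentration [mM]
    G0: float = 0.22           # untreated rate [1/h]
    G_max: float = 0.7         # Monod maximal rate [1/h]
    K_half: float = 20.0       # Monod half-saturation [mM]

    def __post_init__(self) -> None:
        if self.c_inh <= 0 or self.G_max <= 0 or self.K_half <= 0:
            raise ValueError("c_inh, G_max, K_half must be positive")


@dataclass(frozen=True)
class ScalingLaw:
    """Quadratic (or general power) rigidity scaling of the effective rate."""

    A_amp: float = 1.0         # amplitude [1/h / kBT^beta]
    kappa_crit: float = 36.0   # critical rigidity [kBT]
    beta: float = 2.0          # scaling exponent

    def __call__(self, kappa):
        return effective_rate_from_rigidity(kappa, self)[0]


def delayed_exponential(t, params: GrowthParams):
    """Delayed exponential count N(t) = N0*exp(G*(t - t0))."""
    t = np.asarray(t, dtype=float)
    out = params.N0 * np.exp(params.G * (t - params.t0))
    return float(out) if out.ndim == 0 else out


def apparent_inoculum(params: GrowthParams) -> float:
    """Apparent inoculum N0*exp(-G*t0) recovered after the lag phase."""
    return params.N0 * np.exp(-params.G * params.t0)


def doubling_time(G: float) -> float:
    """Doubling time tau_p = ln2/G for a dividing homogeneous population."""
    if G <= 0:
        raise ValueError(f"doubling time requires G > 0, got {G}")
    return LN2 / G


def logistic_od(t, params: GrowthParams):
    """Delayed logistic OD(t) = Q_inf/(1 + ((Q_inf-Q0)/Q0)*exp(-G*(t-t0))).

    Reduces to the delayed exponential with prefactor Q0 at early times
    (OD << Q_inf) and saturates at the stationary plateau Q_inf.
    """
    if params.Q0 >= params.Q_inf:
        raise ValueError("logistic growth requires Q0 < Q_inf")
    t = np.asarray(t, dtype=float)
    r = (params.Q_inf - params.Q0) / params.Q0
    out = params.Q_inf / (1.0 + r * np.exp(-params.G * (t - params.t0)))
    return float(out) if out.ndim == 0 else out


def monod_rate(c, dr: DoseResponse):
    """Monod law G(c) = G_max*c/(K_half + c) (softener dose response)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    out = dr.G_max * c / (dr.K_half + c)
    return float(out) if out.ndim == 0 else out


def linear_inhibition(c, dr: DoseResponse):
    """First-order inhibition G(c) = G0*(1 - c/c_inh), clipped at 0."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    out = np.clip(dr.G0 * (1.0 - c / dr.c_inh), 0.0, None)
    return float(out) if out.ndim == 0 else out


def effective_rate_from_rigidity(kappa, law: ScalingLaw):
    """Effective growth rate G_eff = A*(kappa_crit - kappa)^beta below threshold.

    Returns ``(G_eff, valid)``.  G_eff = 0 at and above kappa_crit
    (inhibition by stiffening exhaustion).  The validity flag is False for
    kappa outside the open interval (0, kappa_crit): kappa <= 0 marks the
    softening-instability boundary, kappa >= kappa_crit the exhaustion one.
    """
    kappa = np.asarray(kappa, dtype=float)
    dk = np.clip(law.kappa_crit - kappa, 0.0, None)
    g = law.A_amp * dk**law.beta
    g = np.where(kappa >= law.kappa_crit, 0.0, g)
    valid = (kappa > 0) & (kappa < law.kappa_crit)
    if g.ndim == 0:
        return float(g), bool(valid)
    return g, valid


def lag_from_alpha(alpha: float, tau_p: float) -> float:
    """Lag time induced by unsuccessful divisions.

    t0 = tau_p*(1/ln(2*alpha) - 1/ln2): zero for fully successful division
    (alpha = 1), diverging as alpha -> 1/2 where the population barely
    replaces itself.
    """
    if not 0.5 < alpha <= 1.0:
        raise ValueError(
            f"alpha must lie in (1/2, 1], got {alpha} (no net proliferation)"
        )
    if tau_p <= 0:
        raise ValueError("tau_p must be positive")
    return tau_p * (1.0 / np.log(2.0 * alpha) - 1.0 / LN2)


@dataclass(frozen=True)
class Subpopulation:
    """One FtsZ-content stratum of a heterogeneous population."""

    name: str
    phenotype: str             # 'normal' | 'filament' | 'dead'
    count: float = 100.0       # initial count [cells]
    mean_length: float = 1.8   # initial mean length [um]
    kappa: float = 12.0        # membrane bending modulus [kBT]
    u: float = 0.3             # FtsZ fraction
    alpha: float = 1.0         # division-success fraction in (1/2, 1]
    rate: float | None = None  # explicit G [1/h]; derived from the law if None
    elongation_rate: float = 0.0   # filament length growth rate [1/h]
    death_rate: float = 0.0        # optional decay of count [1/h]
    division_reentry: float = 0.0  # filament->normal division rate [1/h]

    def __post_init__(self) -> None:
        if self.phenotype not in ("normal", "filament", "dead"):
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.count < 0 or self.mean_length <= 0:
            raise ValueError("count must be >= 0 and mean_length > 0")


@dataclass
class StructuredPopulation:
    """Trajectories of a structured population on a time grid."""

    t: np.ndarray                       # [h]
    counts: dict                        # phenotype -> array over t
    lengths: dict                       # subpop name -> mean length over t
    sub_counts: dict                    # subpop name -> count over t
    biomass: np.ndarray                 # total cell length [um]
    EOD: np.ndarray                     # effective optical density [arb]


def _subpop_rate(sub: Subpopulation, law: ScalingLaw | None,
                 membrane: MembraneParams | None) -> float:
    """Division rate of a normal subpopulation.

    Explicit rate wins; otherwise the rigidity scaling law is evaluated at
    the stratum's kappa, with kappa_crit set by its FtsZ content through the
    constriction model when membrane parameters are supplied.
    """
    if sub.rate is not None:
        return sub.rate
    law = law or ScalingLaw()
    if membrane is not None:
        from .constriction import critical_rigidity

        kc = critical_rigidity(sub.u, membrane)
        law = ScalingLaw(A_amp=law.A_amp, kappa_crit=kc, beta=law.beta)
    g, _ = effective_rate_from_rigidity(sub.kappa, law)
    return g


def simulate_structured(
    subpops: Sequence[Subpopulation],
    t_grid: Sequence[float] | np.ndarray,
    law: ScalingLaw | None = None,
    membrane: MembraneParams | None = None,
    eod_scale: float = 1.0,
    stochastic: bool = False,
    seed: int | None = None,
) -> StructuredPopulation:
    """Propagate a heterogeneous FtsZ-structured population.

    Deterministic linear ODEs by default: normal strata divide at rate
    alpha*G (counts grow exponentially; mean length constant), filaments
    keep constant count while elongating exponentially, dead strata are
    inert; optional death and filament->normal re-entry channels couple the
    strata.  EOD = eod_scale * total length, so a filamenting culture's
    turbidity outruns its cell count.  The stochastic variant runs a
    seeded Gillespie-style birth process for the counts.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be a strictly increasing 1-D array >= 0")
    if len(subpops) == 0:
        raise ValueError("at least one subpopulation is required")

    names = [s.name for s in subpops]
    n = len(subpops)
    rates = np.array(
        [
            _subpop_rate(s, law, membrane) if s.phenotype == "normal" else 0.0
            for s in subpops
        ]
    )
    # state = counts per stratum; linear generator M: dN/dt = M N
    M = np.zeros((n, n))
    for i, s in enumerate(subpops):
        if s.phenotype == "normal":
            M[i, i] += s.alpha * rates[i]
        M[i, i] -= s.death_rate
        if s.phenotype == "filament" and s.division_reentry > 0:
            targets = [
                j for j, o in enumerate(subpops) if o.phenotype == "normal"
            ]
            if targets:
                # a dividing filament sheds a normal daughter, keeps growing
                M[targets[0], i] += s.division_reentry

    N0 = np.array([s.count for s in subpops], float)
    lag = np.array(
        [
            lag_from_alpha(s.alpha, doubling_time(max(rates[i], 1e-12)))
            if (s.phenotype == "normal" and s.alpha < 1.0 and rates[i] > 0)
            else 0.0
            for i, s in enumerate(subpops)
        ]
    )

    rng = np.random.default_rng(seed)
    counts = np.empty((t.size, n))
    if not stochastic:
        for k, tk in enumerate(t):
            # per-stratum lag: the generator switches on after t0
            dt_eff = np.clip(tk - lag, 0.0, None)
            if np.allclose(dt_eff, dt_eff[0]):
                counts[k] = expm(M * dt_eff[0]) @ N0
            else:
                # piecewise-constant activation, strata switched on in order
                state = N0.copy()
                edges = np.unique(np.concatenate([[0.0], lag[lag < tk], [tk]]))
                for a, b in zip(edges[:-1], edges[1:]):
                    Ma = M.copy()
                    for i in range(n):
                        if lag[i] > a + 1e-12:  # stratum still lagging
                            Ma[i, :] = 0.0
                            Ma[:, i] = 0.0
                    state = expm(Ma * (b - a)) @ state
                counts[k] = state
    else:
        state = N0.astype(float).copy()
        now = 0.0
        counts[0] = state
        for k in range(1, t.size):
            while True:
                prop = np.clip(np.diag(M) * state, 0.0, None)
                total = prop.sum()
                if total <= 0:
                    break
                dt = rng.exponential(1.0 / total)
                if now + dt > t[k]:
                    break
                now += dt
                i = rng.choice(n, p=prop / total)
                state[i] += 1.0
            counts[k] = state
            now = t[k]

    lengths = {}
    for i, s in enumerate(subpops):
        if s.phenotype == "filament":
            lengths[s.name] = s.mean_length * np.exp(s.elongation_rate * t)
        else:
            lengths[s.name] = np.full(t.size, s.mean_length)

    sub_counts = {name: counts[:, i] for i, name in enumerate(names)}
    by_pheno = {p: np.zeros(t.size) for p in ("normal", "filament", "dead")}
    for i, s in enumerate(subpops):
        by_pheno[s.phenotype] += counts[:, i]

    biomass = np.zeros(t.size)
    for i, s in enumerate(subpops):
        biomass += counts[:, i] * lengths[s.name]
    return StructuredPopulation(
        t=t, counts=by_pheno, lengths=lengths, sub_counts=sub_counts,
        biomass=biomass, EOD=eod_scale * biomass,
    )


def trajectories_frame(pop: StructuredPopulation):
    """Tabulate a structured-population run as a tidy DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        dict(
            time_h=pop.t,
            count_normal=pop.counts["normal"],
            count_filament=pop.counts["filament"],
            count_dead=pop.counts["dead"],
            biomass_um=pop.biomass,
            EOD=pop.EOD,
        )
    )
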