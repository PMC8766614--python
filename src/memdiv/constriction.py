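"""Linearized FtsZ-driven membrane-constriction stability model.

A rod-shaped bacterium divides when the contractile stress exerted by the
FtsZ ring overcomes the elastic resistance of the cell envelope.  On a
cylindrical cell of radius ``R`` carrying a homogeneous FtsZ membrane
fraction ``u_h``, a small shape perturbation of wavenumber ``q`` along the
cell axis grows or decays at a rate given by the conserved-dynamics
(Cahn–Hilliard-type) dispersion relation

    omega(q) = Lambda * q**2 * (zeta*u_h - sigma_t - kappa/R**2 - kappa*q**2)

where ``kappa`` is the membrane bending modulus, ``sigma_t`` the lateral
tension and ``zeta`` the FtsZ contractile coupling.  The balance of the
contractile drive ``F_c = zeta*u_h`` against the bending/tension resistance
``F_b = sigma_t + kappa/R**2`` defines a critical rigidity
``kappa_crit = R**2 * (zeta*u_h - sigma_t)``: below it the membrane is
linearly unstable and the cell constricts, above it division is hindered.

Units: energies in kBT, lengths in um, rates in 1/h; ``Lambda`` absorbs all
kinetic prefactors (its default of 1 sets the time unit).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "MembraneParams",
    "DispersionResult",
    "CriticalLine",
    "dispersion",
    "critical_rigidity",
    "critical_ftsz",
    "unstable_modes",
    "classify_state",
    "state_diagram",
]


@dataclass(frozen=True)
class MembraneParams:
    """Physical parameters of the constriction stability model.

    Defaults follow the package's reference calibration: bilayer modulus
    kappa_0 = 12 kBT, cell radius 0.5 um, zero excess tension, contractile
    coupling zeta = 480 kBT/um^2 and a regulated FtsZ fraction u_0 = 0.3,
    which place the critical rigidity at 36 kBT = 3*kappa_0.
    """

    kappa: float = 12.0        # bending modulus [kBT]
    sigma_t: float = 0.0       # effective lateral tension [kBT/um^2]
    R: float = 0.5             # cell radius [um]
    L_cell: float = 3.0        # cell length [um]
    Lambda: float = 1.0        # kinetic mobility [um^4/(h*kBT)]
    zeta: float = 480.0        # FtsZ contractile coupling [kBT/um^2]
    u_h: float = 0.3           # homogeneous FtsZ fraction per membrane site
    u_0: float = 0.3           # reference regulated FtsZ level
    kappa_0: float = 12.0      # reference bending modulus [kBT]

    def __post_init__(self) -> None:
        if not np.isfinite(
            [self.kappa, self.sigma_t, self.R, self.L_cell, self.Lambda,
             self.zeta, self.u_h]
        ).all():
            raise ValueError("membrane parameters must be finite")
        if self.kappa <= 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        if self.R <= 0:
            raise ValueError(f"R must be positive, got {self.R}")
        if self.L_cell <= 0:
            raise ValueError(f"L_cell must be positive, got {self.L_cell}")
        if self.Lambda <= 0:
            raise ValueError(f"Lambda must be positive, got {self.Lambda}")
        if self.zeta < 0:
            raise ValueError(f"zeta must be non-negative, got {self.zeta}")
        if not 0.0 <= self.u_h <= 1.0:
            raise ValueError(f"u_h must lie in [0, 1], got {self.u_h}")

    def with_(self, **kwargs) -> "MembraneParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @property
    def F_c(self) -> float:
        """Contractile drive zeta*u_h [kBT/um^2]."""
        return self.zeta * self.u_h

    @property
    def F_b(self) -> float:
        """Bending/tension resistance sigma_t + kappa/R^2 [kBT/um^2]."""
        return self.sigma_t + self.kappa / self.R**2


@dataclass(frozen=True)
class DispersionResult:
    """Growth rate omega(q) on a wavenumber grid plus its closed-form summary."""

    q_grid: np.ndarray          # [1/um]
    omega: np.ndarray           # [1/h]
    F_c: float                  # contractile drive [kBT/um^2]
    F_b: float                  # resistance [kBT/um^2]
    q_star: float               # most-unstable wavenumber [1/um]
    omega_max: float            # maximal growth rate [1/h]
    stable: bool


@dataclass(frozen=True)
class CriticalLine:
    """Critical rigidity/FtsZ boundary evaluated for a parameter set."""

    params: MembraneParams

    def kappa_crit(self, u_h: float | np.ndarray) -> float | np.ndarray:
        return critical_rigidity(u_h, self.params)

    def u_crit(self, kappa: float | np.ndarray) -> float | np.ndarray:
        return critical_ftsz(kappa, self.params)

    def delta_kappa(self, kappa: float | np.ndarray,
                    u_h: float | np.ndarray) -> float | np.ndarray:
        """Rigidity order parameter kappa_crit(u_h) - kappa [kBT]."""
        return critical_rigidity(u_h, self.params) - np.asarray(kappa, float)


def _drive(params: MembraneParams) -> float:
    """Net destabilizing stress A = F_c - F_b [kBT/um^2]."""
    return params.F_c - params.F_b


def dispersion(params: MembraneParams,
               q_grid: Sequence[float] | np.ndarray) -> DispersionResult:
    """Evaluate the dispersion relation omega(q) on a wavenumber grid.

    omega(q) = Lambda*q^2*(A - kappa*q^2) with A = F_c - F_b.  When A > 0
    the fastest-growing mode sits at q_star = sqrt(A/(2*kappa)) with rate
    omega_max = Lambda*A^2/(4*kappa); when A <= 0 every q > 0 decays and
    the membrane is stable (omega_max = 0, q_star = 0 by convention).
    """
    q = np.asarray(q_grid, dtype=float)
    if np.any(q < 0):
        raise ValueError("wavenumbers must be non-negative")
    A = _drive(params)
    omega = params.Lambda * q**2 * (A - params.kappa * q**2)
    if A > 0:
        q_star = float(np.sqrt(A / (2.0 * params.kappa)))
        omega_max = float(params.Lambda * A**2 / (4.0 * params.kappa))
        stable = False
    else:
        # marginal A == 0 counts as stable (non-dividing)
        q_star = 0.0
        omega_max = 0.0
        stable = True
    return DispersionResult(
        q_grid=q, omega=omega, F_c=params.F_c, F_b=params.F_b,
        q_star=q_star, omega_max=omega_max, stable=stable,
    )


def critical_rigidity(u_h: float | np.ndarray,
                      params: MembraneParams) -> float | np.ndarray:
    """Critical bending modulus kappa_crit(u_h) = R^2*(zeta*u_h - sigma_t).

    Above kappa_crit the contractile drive cannot beat the envelope
    resistance and division is hindered.  Clipped at 0 when the drive falls
    below the tension floor.
    """
    u = np.asarray(u_h, dtype=float)
    if np.any(u < 0) or np.any(u > 1):
        raise ValueError("u_h must lie in [0, 1]")
    kc = params.R**2 * (params.zeta * u - params.sigma_t)
    kc = np.clip(kc, 0.0, None)
    return float(kc) if np.isscalar(u_h) else kc


def critical_ftsz(kappa: float | np.ndarray,
                  params: MembraneParams) -> float | np.ndarray:
    """Critical FtsZ fraction u_crit(kappa) = (sigma_t + kappa/R^2)/zeta.

    Inverse of :func:`critical_rigidity` on the critical line.
    """
    k = np.asarray(kappa, dtype=float)
    if np.any(k < 0):
        raise ValueError("kappa must be non-negative")
    if params.zeta == 0:
        raise ValueError("u_crit undefined for zeta = 0 (no contractile drive)")
    uc = (params.sigma_t + k / params.R**2) / params.zeta
    return float(uc) if np.isscalar(kappa) else uc


def unstable_modes(params: MembraneParams, n_max: int = 1000) -> list[int]:
    """Quantized axial modes q_n = n*pi/L_cell with positive growth rate.

    Finite cell length admits only a discrete ladder of wavenumbers; the
    divisional instability requires at least one unstable low-q mode, so
    short cells (q_1 already beyond the unstable band) cannot divide.
    """
    A = _drive(params)
    if A <= 0:
        return []
    q_edge = np.sqrt(A / params.kappa)  # omega > 0 iff 0 < q < q_edge
    n_edge = int(np.floor(q_edge * params.L_cell / np.pi))
    return list(range(1, min(n_edge, n_max) + 1))


def classify_state(kappa: float, u_h: float,
                   params: MembraneParams | None = None) -> str:
    """Label a (kappa, u_h) point with its proliferation region.

    Regions of the state diagram:

    * ``I``   exhausted, near-frozen cells: deeply stable (kappa far above
      the critical line) at strongly subcritical FtsZ;
    * ``II``  rigid cells at hindered constriction: stable but close to the
      critical line, or unstable yet much stiffer than the reference bilayer;
    * ``III`` normally dividing cells: unstable with near-reference rigidity
      and regulated FtsZ;
    * ``IV``  abnormally dividing softened cells: unstable with a strongly
      softened membrane or an FtsZ overload.
    """
    p = (params or MembraneParams()).with_(kappa=max(kappa, 1e-12), u_h=u_h)
    kc = critical_rigidity(u_h, p)
    stable = kappa >= kc or kc == 0.0
    if stable:
        uc0 = critical_ftsz(p.kappa_0, p)
        if kappa > 2.0 * kc and u_h < 0.5 * uc0:
            return "I"
        return "II"
    if kappa < 0.5 * p.kappa_0 or u_h > 2.0 * p.u_0:
        return "IV"
    if kappa <= 2.0 * p.kappa_0:
        return "III"
    return "II"


def state_diagram(kappa_grid: np.ndarray, u_grid: np.ndarray,
                  params: MembraneParams | None = None):
    """Tabulate (kappa, u_h, region, omega_max) on a rectangular grid.

    Returns a pandas DataFrame suitable for CSV export.
    """
    import pandas as pd

    p = params or MembraneParams()
    rows = []
    for u in np.asarray(u_grid, float):
        for k in np.asarray(kappa_grid, float):
            pk = p.with_(kappa=k, u_h=u)
            d = dispersion(pk, np.array([0.0]))
            rows.append(
                dict(kappa=k, u_h=u, region=classify_state(k, u, p),
                     omega_max=d.omega_max)
            )
    return pd.DataFrame(rows)
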