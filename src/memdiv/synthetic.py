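"""Seeded generators for every input the analysis consumes.

All generators are pure functions of (spec, seed): the same arguments give
bit-identical output.  They emulate

* equilibrium + active membrane contour fluctuations with a prescribed
  effective stiffness (per-site variance kBT*A/K, Ornstein-Uhlenbeck in
  time, optional compound-Poisson bursts on "soft" sites);
* phase-contrast-like movies of a fluctuating cell at 50 nm/px, rendered as
  a bright halo ring with a Gaussian radial profile whose steepest inner
  flank sits on the membrane;
* delayed-exponential / logistic growth curves with dose-dependent rates
  (linear inhibition for stiffeners, Monod with a lag ceiling for
  softeners) and Poisson or additive noise;
* bimodal normal/filament cytometry tables;
* master-plot (kappa, G_eff) datasets obeying the quadratic rigidity law
  with multiplicative lognormal noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .flicker import ContourSeries, NM2_PER_UM2
from .kinetics import (
    DoseResponse,
    GrowthParams,
    ScalingLaw,
    delayed_exponential,
    linear_inhibition,
    logistic_od,
    monod_rate,
)

__all__ = [
    "OpticsConfig",
    "ActiveNoiseConfig",
    "gen_contour_series",
    "gen_image_stack",
    "gen_growth_curves",
    "gen_cytometry",
    "gen_master_dataset",
    "gen_guv_modes",
]


@dataclass(frozen=True)
class OpticsConfig:
    """Rendering parameters of the synthetic phase-contrast optics."""

    pixel_size: float = 50.0        # [nm]
    frame_rate: float = 2000.0      # [fps]
    n_frames: int = 4000
    halo_peak: float = 220.0        # halo crest intensity [gray]
    halo_width: float = 250.0       # halo Gaussian width [nm]
    interior_level: float = 20.0    # dark cell interior [gray]
    background_level: float = 20.0  # medium level [gray]
    noise_sd: float = 0.0           # additive Gaussian noise [gray]
    psf_width: float = 0.0          # extra blur, combined in quadrature [nm]
    invert: bool = False            # dark halo on bright background

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate


@dataclass(frozen=True)
class ActiveNoiseConfig:
    """Out-of-equilibrium burst noise on a fraction of 'soft' sites."""

    soft_fraction: float = 0.0      # fraction of sites carrying bursts
    burst_rate: float = 5.0         # [1/s]
    burst_amplitude: float = 5.0    # in multiples of the thermal SD
    correlation_time: float = 0.01  # burst decay time [s]

    def __post_init__(self) -> None:
        if not 0.0 <= self.soft_fraction <= 1.0:
            raise ValueError("soft_fraction must lie in [0, 1]")
        if min(self.burst_rate, self.burst_amplitude,
               self.correlation_time) < 0:
            raise ValueError("active-noise parameters must be non-negative")


def gen_contour_series(
    K_eff: float,
    A_mem: float,
    optics: OpticsConfig | None = None,
    active: ActiveNoiseConfig | None = None,
    seed: int | None = None,
    n_sites: int = 128,
    tau_corr: float = 0.01,
    radius_um: float = 0.5,
    n_spatial_modes: int | None = None,
) -> ContourSeries:
    """Stationary fluctuating contour with per-site variance kBT*A/K.

    Each site follows an Ornstein-Uhlenbeck process in time (correlation
    time ``tau_corr`` seconds) whose stationary SD realizes the
    equipartition amplitude sqrt(kBT*A_mem/K_eff) in nm; soft sites add
    seeded compound-Poisson bursts that fatten the tails (kurtosis > 3)
    without much shifting the variance floor.  ``K_eff`` is capped at
    1e6 kBT, where the amplitude is effectively zero (dead-cell limit).

    With ``n_spatial_modes`` the displacement field is built from that many
    low-order Fourier modes around the contour (m = 2 .. m+1; breathing and
    translation modes excluded) with OU amplitudes, keeping the per-site
    variance exact while making h(x) smooth along arclength — the physical
    situation for bending modes, and the right input for rendering since
    site-to-site white noise lies below the optical resolution.
    """
    if K_eff <= 0 or A_mem <= 0:
        raise ValueError("K_eff and A_mem must be positive")
    K_eff = min(K_eff, 1.0e6)
    optics = optics or OpticsConfig()
    active = active or ActiveNoiseConfig()
    rng = np.random.default_rng(seed)
    n_frames = optics.n_frames
    sigma = np.sqrt(A_mem * NM2_PER_UM2 / K_eff)   # [nm]
    rho = np.exp(-optics.dt / tau_corr)

    def ou(n_series: int, sd: float) -> np.ndarray:
        s_innov = sd * np.sqrt(1.0 - rho**2)
        z = np.empty((n_series, n_frames))
        z[:, 0] = rng.normal(0.0, sd, n_series)
        innov = rng.normal(0.0, s_innov, (n_series, n_frames - 1))
        for t in range(1, n_frames):
            z[:, t] = rho * z[:, t - 1] + innov[:, t - 1]
        return z

    if n_spatial_modes is None:
        h = ou(n_sites, sigma)
    else:
        M = int(n_spatial_modes)
        if M < 1:
            raise ValueError("n_spatial_modes must be >= 1")
        theta = 2.0 * np.pi * np.arange(n_sites) / n_sites
        amp = ou(2 * M, sigma / np.sqrt(M))  # a_m, b_m pairs
        h = np.zeros((n_sites, n_frames))
        for i, m in enumerate(range(2, M + 2)):
            h += np.outer(np.cos(m * theta), amp[2 * i])
            h += np.outer(np.sin(m * theta), amp[2 * i + 1])
        # per-site variance is exact: each mode contributes
        # (sigma^2/M)*(cos^2 + sin^2) = sigma^2/M at every site

    n_soft = int(round(active.soft_fraction * n_sites))
    if n_soft > 0:
        soft = rng.choice(n_sites, n_soft, replace=False)
        rho_b = np.exp(-optics.dt / max(active.correlation_time, optics.dt))
        p_evt = active.burst_rate * optics.dt
        events = rng.random((n_soft, n_frames)) < p_evt
        kicks = (
            events
            * active.burst_amplitude
            * sigma
            * rng.standard_normal((n_soft, n_frames))
        )
        b = np.zeros((n_soft, n_frames))
        for t in range(1, n_frames):
            b[:, t] = rho_b * b[:, t - 1] + kicks[:, t]
        h[soft] += b

    circ = 2.0 * np.pi * radius_um
    x = circ * np.arange(n_sites) / n_sites
    return ContourSeries(
        h=h, x=x, dt=optics.dt, pixel_size=optics.pixel_size,
        fiducial_radius=radius_um,
    )


def gen_image_stack(
    series: ContourSeries,
    optics: OpticsConfig | None = None,
    seed: int | None = None,
    shape: tuple[int, int] | None = None,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Render a contour series as a phase-contrast-like grayscale stack.

    The cell interior is dark and the boundary is marked by a bright halo
    ring with a Gaussian radial profile.  The halo crest is placed one
    effective halo-width outside the instantaneous membrane position, so
    that the steepest inner flank of the halo — the feature the tracker
    locks onto — coincides with the membrane itself.  Any PSF width is
    folded into the halo width in quadrature; Gaussian readout noise is
    added last (seeded).

    Returns a float32 array (n_frames, H, W).
    """
    optics = optics or OpticsConfig()
    rng = np.random.default_rng(seed)
    px = optics.pixel_size
    r_fid_px = np.atleast_1d(np.asarray(series.fiducial_radius, float)) * 1000.0 / px
    if r_fid_px.size == 1:
        r_fid_px = np.full(series.n_sites, r_fid_px[0])
    w_eff_px = np.hypot(optics.halo_width, optics.psf_width) / px

    margin = 4.0 * w_eff_px + 4.0
    r_px_max = (r_fid_px + np.abs(series.h).max() / px).max()
    if shape is None:
        side = int(np.ceil(2.0 * (r_px_max + margin)))
        shape = (side, side)
    H, W = shape
    if center is None:
        center = ((H - 1) / 2.0, (W - 1) / 2.0)
    cy, cx = center
    if r_px_max + 0.5 * margin > min(cy, cx, H - 1 - cy, W - 1 - cx):
        raise ValueError("contour exits the frame: enlarge shape or margin")

    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    dy, dx = yy - cy, xx - cx
    r_pix = np.hypot(dy, dx)
    th_pix = np.arctan2(dy, dx) % (2.0 * np.pi)
    n = series.n_sites
    theta = 2.0 * np.pi * np.arange(n) / n

    amp = optics.halo_peak - optics.background_level
    base = optics.background_level
    stack = np.empty((series.n_frames, H, W), np.float32)
    for f in range(series.n_frames):
        rho = r_fid_px + series.h[:, f] / px
        rho_pix = np.interp(th_pix.ravel(), theta, rho, period=2.0 * np.pi)
        d = r_pix.ravel() - rho_pix                     # [px] outward distance
        img = base + amp * np.exp(-((d - w_eff_px) ** 2) / (2.0 * w_eff_px**2))
        inside = d < 0
        img[inside] += optics.interior_level - optics.background_level
        img = img.reshape(H, W)
        if optics.invert:
            img = (optics.halo_peak + optics.background_level) - img
        if optics.noise_sd > 0:
            img = img + rng.normal(0.0, optics.noise_sd, img.shape)
        stack[f] = img
    return stack


def gen_growth_curves(
    model: Literal["exp", "logistic", "structured"],
    params: GrowthParams,
    t: Sequence[float] | np.ndarray,
    noise: float = 0.0,
    noise_kind: Literal["poisson", "additive", "none"] = "none",
    n_replicates: int = 1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Replicate growth curves from a forward kinetic model.

    Count curves take Poisson noise, OD curves additive Gaussian noise with
    SD = ``noise`` * plateau.  Returns a tidy frame with columns
    (time_h, value, kind, replicate).
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(t, float)
    frames = []
    for rep in range(n_replicates):
        if model == "exp":
            y = delayed_exponential(t, params)
            kind = "count"
        elif model == "logistic":
            y = logistic_od(t, params)
            kind = "od"
        else:
            raise ValueError(f"unknown model {model!r}")
        if noise_kind == "poisson":
            y = rng.poisson(np.clip(y, 0, None)).astype(float)
        elif noise_kind == "additive":
            y = y + rng.normal(0.0, noise * params.Q_inf, t.shape)
        frames.append(
            pd.DataFrame(dict(time_h=t, value=y, kind=kind, replicate=rep))
        )
    return pd.concat(frames, ignore_index=True)


def gen_dose_series(
    kind: Literal["stiffener", "softener"],
    dr: DoseResponse,
    c_values: Sequence[float],
    t: Sequence[float] | np.ndarray,
    params: GrowthParams | None = None,
    lag_ceiling: float = 6.0,
    lag_half_dose: float = 10.0,
    noise: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Dose series of OD curves with dose-dependent rate and lag.

    Stiffener-like: rate falls linearly to zero at c_inh, lag stays at the
    untreated value.  Softener-like: rate follows the Monod law (floored at
    the untreated rate) while the lag rises saturably to ``lag_ceiling``.
    """
    params = params or GrowthParams()
    rng = np.random.default_rng(seed)
    out = []
    for c in c_values:
        if kind == "stiffener":
            g = linear_inhibition(c, dr)
            t0 = params.t0
        elif kind == "softener":
            g = max(monod_rate(c, dr), dr.G0)
            t0 = lag_ceiling * c / (lag_half_dose + c)
        else:
            raise ValueError(f"unknown dose kind {kind!r}")
        p = GrowthParams(
            N0=params.N0, G=g, t0=t0, Q0=params.Q0, Q_inf=params.Q_inf
        )
        tt = np.asarray(t, float)
        y = (
            logistic_od(tt, p)
            if g > 0
            else np.full(tt.shape, params.Q0)
        )
        if noise > 0:
            y = y + rng.normal(0.0, noise * params.Q_inf, tt.shape)
        out.append(
            pd.DataFrame(
                dict(time_h=tt, value=y, kind="od", replicate=0, dose=c)
            )
        )
    return pd.concat(out, ignore_index=True)


def gen_cytometry(
    n: int,
    filament_fraction: float = 0.0,
    L0: float = 1.8,
    sigma_L: float = 0.5,
    D0: float = 0.52,
    sigma_D: float = 0.15,
    filament_mean: float = 6.0,
    filament_sigma_log: float = 0.5,
    filament_min: float = 3.0,
    condition: str = "untreated",
    time_h: float = 2.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Bimodal cytometry table: normal truncated-Gaussian pool + filaments.

    Normal cells draw lengths from N(L0, sigma_L) truncated at > 0 and
    widths from N(D0, sigma_D) truncated at > 0; filaments draw lengths
    from a lognormal with the given arithmetic mean, truncated above
    ``filament_min`` (slightly slender widths).  Columns:
    (length_um, width_um, time_h, condition).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= filament_fraction <= 1.0:
        raise ValueError("filament_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_fil = int(round(filament_fraction * n))
    n_norm = n - n_fil

    def trunc_normal(mu, sd, size, low=0.0):
        out = np.empty(size)
        todo = np.arange(size)
        while todo.size:
            draw = rng.normal(mu, sd, todo.size)
            good = draw > low
            out[todo[good]] = draw[good]
            todo = todo[~good]
        return out

    L = trunc_normal(L0, sigma_L, n_norm)
    D = trunc_normal(D0, sigma_D, n_norm)
    if n_fil > 0:
        # lognormal mu set so the untruncated arithmetic mean is filament_mean
        mu = np.log(filament_mean) - 0.5 * filament_sigma_log**2
        Lf = np.empty(n_fil)
        todo = np.arange(n_fil)
        while todo.size:
            draw = rng.lognormal(mu, filament_sigma_log, todo.size)
            good = draw > filament_min
            Lf[todo[good]] = draw[good]
            todo = todo[~good]
        Df = trunc_normal(0.9 * D0, sigma_D, n_fil)
        L = np.concatenate([L, Lf])
        D = np.concatenate([D, Df])
    return pd.DataFrame(
        dict(length_um=L, width_um=D, time_h=time_h, condition=condition)
    )


def gen_master_dataset(
    A_amp: float = 1.0,
    kappa_crit: float = 36.0,
    beta: float = 2.0,
    kappa_grid: Sequence[float] | np.ndarray | None = None,
    noise_sd: float = 0.15,
    seed: int | None = None,
) -> pd.DataFrame:
    """(kappa, G_eff) master-plot points with lognormal multiplicative noise.

    The default grid is 12 kappa values uniform in [4, 34] kBT, spanning the
    rigidity deficit over about a decade below the 36 kBT threshold.
    """
    if kappa_grid is None:
        kappa_grid = np.linspace(4.0, 34.0, 12)
    kappa = np.asarray(kappa_grid, float)
    if kappa.size < 2:
        raise ValueError("kappa grid must contain at least 2 points")
    if np.any(kappa >= kappa_crit):
        raise ValueError("kappa grid must lie below kappa_crit")
    rng = np.random.default_rng(seed)
    law = ScalingLaw(A_amp=A_amp, kappa_crit=kappa_crit, beta=beta)
    g = law(kappa)
    if noise_sd > 0:
        g = g * np.exp(rng.normal(0.0, noise_sd, kappa.shape))
    return pd.DataFrame(dict(kappa=kappa, G_eff=g, condition="synthetic"))


def gen_guv_modes(
    kappa: float,
    sigma_t: float,
    area: float,
    n_modes: int = 20,
    n_frames: int = 2000,
    radius_um: float = 10.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vesicle contour Fourier amplitudes from the equipartition spectrum.

    Modes q_n = n / R; each complex amplitude is drawn i.i.d. per frame with
    <|h_q|^2> = kBT/(area*(kappa*q^4 + sigma_t*q^2)).  Returns (amps, q).
    """
    rng = np.random.default_rng(seed)
    n_arr = np.arange(1, n_modes + 1)
    q = n_arr / radius_um
    var = 1.0 / (area * (kappa * q**4 + sigma_t * q**2))
    s = np.sqrt(var / 2.0)
    amps = s[:, None] * (
        rng.standard_normal((n_modes, n_frames))
        + 1j * rng.standard_normal((n_modes, n_frames))
    )
    return amps, q
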