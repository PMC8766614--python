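"""Parameter estimation from growth-curve, cytometry and master-plot tables.

Nonlinear least-squares fitters (lmfit under the hood) for the forward
models in :mod:`memdiv.kinetics`, cytometric phenotype classification with
a biomass index, cross-method rate correlation, and the master-scaling fit
G_eff = A*(kappa_crit - kappa)**beta with bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from .kinetics import GrowthParams, ScalingLaw

__all__ = [
    "GrowthCurve",
    "CytometryTable",
    "FitResult",
    "MasterFit",
    "fit_delayed_exponential",
    "fit_logistic",
    "fit_monod",
    "fit_master_scaling",
    "classify_cells",
    "correlate_rates",
]

FILAMENT_THRESHOLD_UM = 2.9   # L0 + sigma_L for the untreated strain


@dataclass
class GrowthCurve:
    """One growth-curve time series (counts or optical density)."""

    t: np.ndarray
    y: np.ndarray
    y_kind: str = "count"     # 'count' | 'od'
    replicate: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.y = np.asarray(self.y, float)
        if self.t.ndim != 1 or self.t.shape != self.y.shape:
            raise ValueError("t and y must be matching 1-D arrays")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if self.y_kind not in ("count", "od"):
            raise ValueError("y_kind must be 'count' or 'od'")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, replicate: int | None = None):
        """Build from a tidy (time_h, value, kind, replicate) frame."""
        if replicate is not None:
            df = df[df["replicate"] == replicate]
        kind = str(df["kind"].iloc[0])
        return cls(
            t=df["time_h"].to_numpy(),
            y=df["value"].to_numpy(),
            y_kind=kind,
            replicate=int(df["replicate"].iloc[0]) if "replicate" in df else 0,
        )


@dataclass
class CytometryTable:
    """Cell length/width table with the population Gaussian parameters."""

    L: np.ndarray
    D: np.ndarray | None = None
    time_h: float | None = None
    condition: str = ""
    L0: float = 1.9
    sigma_L: float = 1.0

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, float)
        if np.any(self.L <= 0):
            raise ValueError("cell lengths must be positive")
        if self.D is not None:
            self.D = np.asarray(self.D, float)
            if np.any(self.D <= 0):
                raise ValueError("cell widths must be positive")


@dataclass
class FitResult:
    """Point estimates with standard errors from the fit covariance."""

    params: dict
    stderr: dict
    success: bool
    warn: str | None = None
    lmfit_result: object = field(default=None, repr=False)

    def __getitem__(self, key):
        return self.params[key]


def _check_curve(curve: GrowthCurve, kind: str, min_points: int = 5) -> None:
    if curve.y_kind != kind:
        raise ValueError(f"expected a {kind!r} curve, got {curve.y_kind!r}")
    if curve.t.size < min_points:
        raise ValueError(
            f"need at least {min_points} points for a fit, got {curve.t.size}"
        )


def fit_delayed_exponential(curve: GrowthCurve,
                            N0: float | None = None) -> FitResult:
    """Fit N(t) = N0*exp(G*(t - t0)) to a count curve.

    Residuals are taken on log N (variance-stabilizing for multiplicative
    growth).  The delayed exponential is a two-parameter family — only the
    apparent inoculum ``N0*exp(-G*t0)`` and ``G`` are identifiable from the
    curve itself — so the lag is resolved only when the true inoculum
    ``N0`` is supplied (as it is in a seeded culture).  Without it the fit
    returns the apparent inoculum with ``t0 = 0`` and a warning.
    """
    _check_curve(curve, "count")
    if np.any(curve.y <= 0):
        raise ValueError("counts must be positive for a log-scale fit")
    logy = np.log(curve.y)
    g0 = max((logy[-1] - logy[0]) / (curve.t[-1] - curve.t[0]), 1e-3)

    p = lmfit.Parameters()
    p.add("G", value=g0, min=0.0)
    if N0 is not None:
        p.add("t0", value=0.1, min=0.0, max=float(curve.t[-1]))

        def resid(pars):
            return (
                np.log(N0) + pars["G"] * (curve.t - pars["t0"]) - logy
            )
    else:
        p.add("logN0app", value=float(logy[0]))

        def resid(pars):
            return pars["logN0app"] + pars["G"] * curve.t - logy

    out = lmfit.minimize(resid, p)
    if not out.success:
        raise RuntimeError(
            "delayed-exponential fit failed: "
            f"{out.message}; residual norm {np.linalg.norm(out.residual):.3g}"
        )
    pr = out.params
    if N0 is not None:
        params = dict(N0=float(N0), G=float(pr["G"].value),
                      t0=float(pr["t0"].value))
        stderr = dict(N0=0.0, G=pr["G"].stderr, t0=pr["t0"].stderr)
        warn = None
    else:
        n0app = float(np.exp(pr["logN0app"].value))
        params = dict(N0=n0app, G=float(pr["G"].value), t0=0.0)
        stderr = dict(
            N0=n0app * (pr["logN0app"].stderr or np.nan),
            G=pr["G"].stderr, t0=None,
        )
        warn = ("lag degenerate with the inoculum: reported N0 is the "
                "apparent inoculum, t0 set to 0; supply N0 to resolve")
    return FitResult(params, stderr, True, warn=warn, lmfit_result=out)


def fit_logistic(curve: GrowthCurve, Q0: float | None = None) -> FitResult:
    """Fit the delayed logistic OD(t) to a turbidity curve.

    Untransformed residuals; Q_inf is constrained to at least the largest
    observation.  Like the delayed exponential, the logistic depends on
    (Q0, t0) only through the half-rise time t0 + ln((Q_inf-Q0)/Q0)/G, so
    the lag is resolved only when the inoculum turbidity ``Q0`` is supplied
    (it is known from the seeding dilution); otherwise both are fitted and
    the reported t0 carries a degeneracy warning.  Curves that never
    approach a plateau return estimates with a wide-SE warning instead of
    failing.
    """
    _check_curve(curve, "od")
    y = curve.y
    t = curve.t
    ymax = float(np.max(y))
    # initialize from the curve shape: the logistic inflection sits at
    # Q_inf/2 with slope G*Q_inf/4
    dy = np.gradient(y, t)
    k_infl = int(np.argmax(dy))
    g0 = max(4.0 * float(dy[k_infl]) / ymax, 1e-3)
    p = lmfit.Parameters()
    p.add("Q_inf", value=ymax * 1.02, min=ymax, max=10.0 * ymax)
    if Q0 is not None:
        if Q0 >= ymax:
            raise ValueError("known Q0 must lie below the largest observation")
        p.add("Q0", value=float(Q0), vary=False)
    else:
        p.add("Q0", value=np.clip(float(y[0]), 1e-6 * ymax, 0.5 * ymax),
              min=1e-9 * ymax, max=ymax)
    p.add("G", value=g0, min=1e-6)
    # t0 is where OD crosses Q0, one logit width before the inflection
    r0 = (p["Q_inf"].value - p["Q0"].value) / p["Q0"].value
    t0_init = np.clip(float(t[k_infl]) - np.log(r0) / g0, 0.0, float(t[-1]))
    p.add("t0", value=t0_init, min=0.0, max=float(t[-1]))

    def resid(pars):
        r = (pars["Q_inf"] - pars["Q0"]) / pars["Q0"]
        model = pars["Q_inf"] / (
            1.0 + r * np.exp(-pars["G"] * (t - pars["t0"]))
        )
        return model - y

    out = lmfit.minimize(resid, p)
    pr = out.params
    params = {k: float(pr[k].value) for k in ("Q0", "Q_inf", "G", "t0")}
    stderr = {k: pr[k].stderr for k in ("Q0", "Q_inf", "G", "t0")}
    warn = None
    if Q0 is None:
        warn = ("lag degenerate with inoculum turbidity: supply Q0 to "
                "resolve t0")
    if y[-1] < 0.8 * params["Q_inf"]:
        warn = "no plateau reached: Q_inf and G weakly identified"
    return FitResult(params, stderr, bool(out.success), warn=warn,
                     lmfit_result=out)


def fit_monod(c: Sequence[float], G: Sequence[float]) -> FitResult:
    """Fit the Monod law G = G_max*c/(K_half + c) to dose-response data."""
    c = np.asarray(c, float)
    G = np.asarray(G, float)
    if c.size < 3:
        raise ValueError("need at least 3 dose levels")
    if np.allclose(G, G[0]):
        raise ValueError("all rates equal: Monod parameters unidentifiable")
    p = lmfit.Parameters()
    p.add("G_max", value=float(np.max(G) * 1.2), min=1e-9)
    p.add("K_half", value=float(np.median(c)), min=1e-9)

    def resid(pars):
        return pars["G_max"] * c / (pars["K_half"] + c) - G

    out = lmfit.minimize(resid, p)
    pr = out.params
    return FitResult(
        dict(G_max=float(pr["G_max"].value), K_half=float(pr["K_half"].value)),
        dict(G_max=pr["G_max"].stderr, K_half=pr["K_half"].stderr),
        bool(out.success),
        lmfit_result=out,
    )


@dataclass
class MasterFit:
    """Joint and conditional estimates of the rigidity scaling law."""

    law: ScalingLaw
    stderr: dict
    beta_conditional: float           # log-log slope at fixed kappa_crit
    bootstrap_ci: dict | None = None  # param -> (lo, hi)
    warn: str | None = None


def fit_master_scaling(
    data: pd.DataFrame,
    fix_beta: float | None = None,
    kappa_crit_for_slope: float | None = None,
    n_bootstrap: int = 0,
    seed: int | None = None,
) -> MasterFit:
    """Fit G_eff = A*(kappa_crit - kappa)**beta to master-plot points.

    ``data`` needs columns (kappa, G_eff).  The joint fit minimizes
    residuals of log G_eff over (A, kappa_crit, beta), with kappa_crit
    bounded below by the largest kappa observed; ``fix_beta`` freezes the
    exponent.  The conditional estimate is the ordinary log-log slope of
    G_eff against (kappa_crit - kappa) at a given (or the fitted)
    kappa_crit.  Optional pair-resampling bootstrap (seeded) yields
    percentile CIs.
    """
    kappa = np.asarray(data["kappa"], float)
    g = np.asarray(data["G_eff"], float)
    if kappa.size < 5:
        raise ValueError("need at least 5 (kappa, G_eff) pairs")
    if np.any(g <= 0):
        raise ValueError("G_eff must be positive for a log-scale fit")
    dk_span = (kappa.max() - kappa.min())
    if dk_span <= 0:
        raise ValueError("kappa values are degenerate")

    def _joint(kp, gg):
        p = lmfit.Parameters()
        kmax = float(np.max(kp))
        p.add("log_A", value=0.0)
        p.add("kappa_crit", value=kmax * 1.1 + 1.0, min=kmax + 1e-6)
        p.add("beta", value=2.0, min=0.1, max=10.0,
              vary=fix_beta is None)
        if fix_beta is not None:
            p["beta"].set(value=fix_beta)

        def resid(pars):
            dk = pars["kappa_crit"] - kp
            return (
                pars["log_A"] + pars["beta"] * np.log(dk) - np.log(gg)
            )

        return lmfit.minimize(resid, p)

    out = _joint(kappa, g)
    pr = out.params
    kc = float(pr["kappa_crit"].value)
    if np.all(kappa >= kc):
        raise ValueError("all kappa at or above the fitted kappa_crit")
    law = ScalingLaw(
        A_amp=float(np.exp(pr["log_A"].value)),
        kappa_crit=kc,
        beta=float(pr["beta"].value),
    )
    stderr = dict(
        A_amp=float(np.exp(pr["log_A"].value)) * (pr["log_A"].stderr or np.nan),
        kappa_crit=pr["kappa_crit"].stderr,
        beta=pr["beta"].stderr,
    )

    kc_slope = kappa_crit_for_slope if kappa_crit_for_slope is not None else kc
    dk = kc_slope - kappa
    sl = stats.linregress(np.log(dk), np.log(g))
    beta_cond = float(sl.slope)

    ci = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        draws = {"A_amp": [], "kappa_crit": [], "beta": []}
        n = kappa.size
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, n)
            if np.unique(kappa[idx]).size < 3:
                continue
            try:
                ob = _joint(kappa[idx], g[idx])
            except Exception:
                continue
            draws["A_amp"].append(np.exp(ob.params["log_A"].value))
            draws["kappa_crit"].append(ob.params["kappa_crit"].value)
            draws["beta"].append(ob.params["beta"].value)
        ci = {
            k: tuple(np.percentile(v, [2.5, 97.5]))
            for k, v in draws.items() if len(v) > 10
        }

    warn = None
    min_dk = float(np.min(kc - kappa))
    if min_dk > 0.5 * kc:
        warn = (
            "kappa grid far from threshold: kappa_crit weakly identified"
        )
    return MasterFit(law=law, stderr=stderr, beta_conditional=beta_cond,
                     bootstrap_ci=ci, warn=warn)


def classify_cells(
    table: CytometryTable | pd.DataFrame,
    threshold: float = FILAMENT_THRESHOLD_UM,
    field_area: float | None = None,
):
    """Partition cells into normal/filament phenotypes by length.

    Normal iff L <= threshold (default 2.9 um = L0 + sigma_L for the
    untreated strain; a cell exactly at threshold counts as normal).  When
    a microscopy field area (um^2) is given and widths are present, the
    biomass index Sum(L_i*D_i)/field_area is returned as the fractional
    surface coverage of rectangle-approximated cell footprints.
    """
    if isinstance(table, pd.DataFrame):
        table = CytometryTable(
            L=table["length_um"].to_numpy(),
            D=table["width_um"].to_numpy() if "width_um" in table else None,
        )
    is_normal = table.L <= threshold
    counts = {
        "normal": int(is_normal.sum()),
        "filament": int((~is_normal).sum()),
    }
    biomass_index = None
    warn = None
    if field_area is not None and table.D is not None:
        biomass_index = float(np.sum(table.L * table.D) / field_area)
    elif field_area is None:
        warn = "field area missing: biomass index omitted"
    return counts, biomass_index, warn


def correlate_rates(G_x: Sequence[float], G_y: Sequence[float]):
    """OLS line and Pearson r between two routes of rate measurement."""
    x = np.asarray(G_x, float)
    y = np.asarray(G_y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)
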