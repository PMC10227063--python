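"""Quantitative analysis of transport and binding assays.

Covers the functional characterization of a Ca2+/phosphate co-transporter:

* Michaelis-Menten fits of initial transport rates, v = Vmax S/(Km + S),
  and fold-acceleration ratios between conditions;
* co-transport stoichiometry as the through-origin least-squares slope of
  paired per-time-point rates, with a bootstrap confidence interval;
* one-site binding isotherms for calorimetric titrations (quadratic 1:1
  equilibrium with per-injection dilution bookkeeping);
* single-exponential luminescence lifetimes and donor-acceptor distances
  via the Forster equation R = R0 [tau_DA / (tau_D - tau_DA)]^(1/6);
* phosphate ionization: the mono-anion fraction from the
  Henderson-Hasselbalch two-species equilibrium (pKa 7.2), and the pH of
  maximal transport from a discrete pH series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "KineticFit",
    "BindingFit",
    "LifetimeFit",
    "LretMeasurement",
    "SpeciationParams",
    "fit_michaelis_menten",
    "fold_acceleration",
    "estimate_stoichiometry",
    "one_site_heats",
    "fit_itc_one_site",
    "fit_lifetime",
    "forster_distance",
    "phosphate_speciation",
    "ph_profile_peak",
]


# -- Michaelis-Menten ------------------------------------------------------


@dataclass
class KineticFit:
    """Michaelis-Menten parameters with standard errors and 95% CIs."""

    km: float
    vmax: float
    km_se: float
    vmax_se: float
    km_ci95: tuple[float, float]
    vmax_ci95: tuple[float, float]
    converged: bool
    n_points: int
    rss: float

    def __post_init__(self) -> None:
        if self.converged and (self.km <= 0 or self.vmax <= 0):
            raise ValueError("km and vmax must be positive for a converged fit")


def fit_michaelis_menten(rates: pd.DataFrame) -> KineticFit:
    """Nonlinear least squares of v = Vmax S / (Km + S).

    ``rates`` needs columns ``conc`` and ``rate`` (replicates as extra
    rows).  The fit is log-parameterized so Km, Vmax > 0 by construction;
    initial guesses are Vmax = max(v) and Km = S at half-maximal rate.
    Non-convergence is flagged, never silently replaced.
    """
    s = np.asarray(rates["conc"], dtype=float)
    v = np.asarray(rates["rate"], dtype=float)
    if np.unique(s).size < 4:
        raise ValueError("need at least 4 distinct substrate concentrations")
    if np.any(v < 0) and np.all(v <= 0):
        raise ValueError("rates must not be all non-positive")

    vmax0 = float(np.max(v))
    if vmax0 <= 0:
        return KineticFit(np.nan, np.nan, np.nan, np.nan, (np.nan, np.nan),
                          (np.nan, np.nan), converged=False, n_points=s.size,
                          rss=float(np.sum(v**2)))
    half = np.abs(v - vmax0 / 2.0)
    km0 = float(s[np.argmin(half)]) or float(np.median(s))

    def model(log_params: np.ndarray) -> np.ndarray:
        km, vmax = np.exp(log_params)
        return vmax * s / (km + s) - v

    try:
        res = optimize.least_squares(model, x0=np.log([km0, vmax0]), method="lm")
    except Exception:
        return KineticFit(np.nan, np.nan, np.nan, np.nan, (np.nan, np.nan),
                          (np.nan, np.nan), converged=False, n_points=s.size,
                          rss=float(np.sum(v**2)))
    km, vmax = np.exp(res.x)
    dof = max(s.size - 2, 1)
    rss = float(res.cost * 2.0)
    # covariance of the log parameters, scaled by the residual variance
    jtj = res.jac.T @ res.jac
    ok = res.success and np.isfinite(jtj).all() and np.linalg.cond(jtj) < 1e12
    if ok:
        cov_log = np.linalg.inv(jtj) * rss / dof
        se_log = np.sqrt(np.diag(cov_log))
        tval = stats.t.ppf(0.975, dof)
        km_se = km * se_log[0]
        vmax_se = vmax * se_log[1]
        km_ci = (km * math.exp(-tval * se_log[0]), km * math.exp(tval * se_log[0]))
        vmax_ci = (vmax * math.exp(-tval * se_log[1]), vmax * math.exp(tval * se_log[1]))
        return KineticFit(float(km), float(vmax), float(km_se), float(vmax_se),
                          km_ci, vmax_ci, converged=True, n_points=s.size, rss=rss)
    return KineticFit(float(km), float(vmax), np.nan, np.nan, (np.nan, np.nan),
                      (np.nan, np.nan), converged=False, n_points=s.size, rss=rss)


def fold_acceleration(fit_plus: KineticFit, fit_minus: KineticFit) -> tuple[float, float]:
    """Vmax ratio (+cofactor / -cofactor) with first-order error propagation."""
    if not (fit_plus.converged and fit_minus.converged):
        raise ValueError("both fits must have converged")
    if fit_minus.vmax == 0:
        raise ZeroDivisionError("reference Vmax is zero")
    ratio = fit_plus.vmax / fit_minus.vmax
    rel = math.hypot(fit_plus.vmax_se / fit_plus.vmax,
                     fit_minus.vmax_se / fit_minus.vmax)
    return ratio, ratio * rel


# -- stoichiometry ---------------------------------------------------------


def estimate_stoichiometry(
    paired: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Through-origin OLS slope of pi_rate on ca_rate, with bootstrap 95% CI.

    ``paired`` needs columns ``ca_rate`` and ``pi_rate`` at matched time
    points.  slope = sum(x y) / sum(x^2); the CI resamples pairs.
    """
    x = np.asarray(paired["ca_rate"], dtype=float)
    y = np.asarray(paired["pi_rate"], dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 paired points")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("all Ca rates are zero")
    slope = float(np.sum(x * y) / sxx)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    bx, by = x[idx], y[idx]
    boots = np.sum(bx * by, axis=1) / np.sum(bx * bx, axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return slope, (float(lo), float(hi))


# -- isothermal titration calorimetry --------------------------------------


def one_site_heats(
    kd: float,
    delta_h: float,
    n_sites: float,
    cell_conc: float,
    syringe_conc: float,
    injection_volume: float,
    n_injections: int,
    cell_volume: float = 1.4e-3,
    offset: float = 0.0,
) -> np.ndarray:
    """Predicted per-injection heats (ucal) for a single-site titration.

    Concentrations in M, volumes in L, delta_h in kcal/mol.  Total
    concentrations follow the standard perfusion-cell dilution bookkeeping;
    the bound concentration solves the 1:1 quadratic equilibrium at each
    step, and the injection heat is the change in cell heat content with a
    displaced-volume correction plus a constant per-injection offset.
    """
    q_prev = 0.0
    heats = np.empty(n_injections)
    for i in range(1, n_injections + 1):
        f = i * injection_volume / cell_volume
        mt = cell_conc * (1.0 - f / 2.0) / (1.0 + f / 2.0)
        xt = syringe_conc * f / (1.0 + f / 2.0)
        b = n_sites * mt + xt + kd
        bound = (b - math.sqrt(max(b * b - 4.0 * n_sites * mt * xt, 0.0))) / 2.0
        q = bound * delta_h * cell_volume  # kcal
        dv = injection_volume / cell_volume
        heats[i - 1] = (q - q_prev + dv * (q + q_prev) / 2.0) * 1e9 + offset
        q_prev = q
    return heats


@dataclass
class BindingFit:
    """One-site binding parameters from an isotherm fit."""

    kd: float
    delta_h: float
    n_sites: float
    offset: float
    kd_se: float
    kd_ci95: tuple[float, float]
    converged: bool
    c_value: float
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.converged and self.kd <= 0:
            raise ValueError("kd must be positive for a converged fit")


def fit_itc_one_site(
    heats: pd.DataFrame,
    cell_conc: float,
    syringe_conc: float,
    injection_volume: float,
    cell_volume: float = 1.4e-3,
    fix_n: float | None = None,
) -> BindingFit:
    """Least-squares fit of the single-site isotherm to injection heats.

    ``heats`` needs columns ``injection`` and ``heat_ucal``.  Parameters
    are (Kd, delta H, n, offset), with Kd log-parameterized; pass ``fix_n``
    to pin the site number (standard practice in the low-c regime, where n
    and delta H are strongly correlated).  The Wiseman c-value
    n * cell_conc / Kd is reported and flagged when outside [0.01, 1e4].
    """
    y = np.asarray(heats["heat_ucal"], dtype=float)
    n_inj = y.size
    if n_inj < 5:
        raise ValueError("need at least 5 injections")

    dh0 = float(y[0] / (cell_conc * cell_volume * 1e9) * 2.0) or -1.0
    kd0 = max(cell_conc, syringe_conc / 20.0)

    def predict(kd: float, dh: float, n: float, offset: float) -> np.ndarray:
        return one_site_heats(kd, dh, n, cell_conc, syringe_conc,
                              injection_volume, n_inj, cell_volume, offset)

    if fix_n is None:
        def resid(p):
            return predict(math.exp(p[0]), p[1], math.exp(p[2]), p[3]) - y
        x0 = np.array([math.log(kd0), dh0, 0.0, 0.0])
    else:
        def resid(p):
            return predict(math.exp(p[0]), p[1], fix_n, p[2]) - y
        x0 = np.array([math.log(kd0), dh0, 0.0])

    flags: list[str] = []
    try:
        res = optimize.least_squares(resid, x0=x0, method="lm", max_nfev=20000)
    except Exception:
        return BindingFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                          (np.nan, np.nan), converged=False, c_value=np.nan,
                          flags=["optimizer_error"])
    kd = math.exp(res.x[0])
    dh = float(res.x[1])
    n = fix_n if fix_n is not None else math.exp(res.x[2])
    offset = float(res.x[-1])
    rss = float(2.0 * res.cost)
    dof = max(n_inj - res.x.size, 1)
    jtj = res.jac.T @ res.jac
    ok = res.success and np.isfinite(jtj).all() and np.linalg.cond(jtj) < 1e12
    if not ok:
        flags.append("ill_conditioned")
    c_value = n * cell_conc / kd
    if not 0.01 <= c_value <= 1e4:
        flags.append("c_value_out_of_range")
    if ok:
        se_log_kd = math.sqrt(np.linalg.inv(jtj)[0, 0] * rss / dof)
        tval = stats.t.ppf(0.975, dof)
        kd_se = kd * se_log_kd
        kd_ci = (kd * math.exp(-tval * se_log_kd), kd * math.exp(tval * se_log_kd))
    else:
        kd_se, kd_ci = np.nan, (np.nan, np.nan)
    return BindingFit(kd=float(kd), delta_h=dh, n_sites=float(n), offset=offset,
                      kd_se=kd_se, kd_ci95=kd_ci, converged=bool(ok),
                      c_value=float(c_value), flags=flags)


# -- luminescence lifetimes and distances ----------------------------------


@dataclass
class LifetimeFit:
    """Single-exponential decay fit y = A exp(-t/tau) + baseline."""

    tau: float
    tau_se: float
    amplitude: float
    baseline: float
    converged: bool
    flags: list[str] = field(default_factory=list)


def fit_lifetime(decay: pd.DataFrame) -> LifetimeFit:
    """Fit a single-exponential decay; flags non-decaying traces.

    ``decay`` needs columns ``t`` and ``y`` with >=10 points spanning at
    least two lifetimes.
    """
    t = np.asarray(decay["t"], dtype=float)
    y = np.asarray(decay["y"], dtype=float)
    if t.size < 10:
        raise ValueError("need at least 10 points")
    a0 = float(y.max() - y.min())
    b0 = float(y.min())
    if a0 <= 0 or y[0] <= y[-1]:
        return LifetimeFit(np.nan, np.nan, np.nan, np.nan, converged=False,
                           flags=["non_decaying"])
    # crude tau from the time to fall to 1/e of the initial span
    target = b0 + a0 / math.e
    below = np.nonzero(y <= target)[0]
    tau0 = float(t[below[0]]) if below.size else float(t[-1] / 3.0)
    tau0 = max(tau0, float(t[1] - t[0]))

    def model(tt, a, tau, b):
        return a * np.exp(-tt / tau) + b

    try:
        popt, pcov = optimize.curve_fit(model, t, y, p0=[a0, tau0, b0], maxfev=20000)
    except Exception:
        return LifetimeFit(np.nan, np.nan, np.nan, np.nan, converged=False,
                           flags=["optimizer_error"])
    a, tau, b = popt
    if tau <= 0 or t.max() < 2.0 * tau:
        return LifetimeFit(float(tau), np.nan, float(a), float(b),
                           converged=False, flags=["trace_too_short"])
    tau_se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.nan
    return LifetimeFit(float(tau), tau_se, float(a), float(b), converged=True)


@dataclass
class LretMeasurement:
    """Donor-only and donor-acceptor lifetimes plus the Forster radius."""

    tau_d: float
    tau_da: float
    r0: float

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("Forster radius must be positive")
        if not 0 < self.tau_da < self.tau_d:
            raise ValueError("need 0 < tau_DA < tau_D")


def forster_distance(m: LretMeasurement) -> float:
    """Donor-acceptor distance R = R0 [tau_DA / (tau_D - tau_DA)]^(1/6)."""
    return m.r0 * (m.tau_da / (m.tau_d - m.tau_da)) ** (1.0 / 6.0)


def tau_da_for_distance(r: float, r0: float, tau_d: float) -> float:
    """Invert the Forster equation: the tau_DA implied by a distance."""
    if r <= 0 or r0 <= 0 or tau_d <= 0:
        raise ValueError("distances and lifetimes must be positive")
    ratio = (r / r0) ** 6
    return tau_d * ratio / (1.0 + ratio)


# -- phosphate speciation and pH profile -----------------------------------


@dataclass
class SpeciationParams:
    """Mono-anion / di-anion phosphate equilibrium constant."""

    pka: float = 7.2

    def __post_init__(self) -> None:
        if not 0.0 < self.pka < 14.0:
            raise ValueError("pKa must be in (0, 14)")


def phosphate_speciation(ph: float, p: SpeciationParams | None = None) -> float:
    """Fraction of phosphate in the mono-anionic form at a given pH.

    Henderson-Hasselbalch two-species approximation:
    f = 1 / (1 + 10^(pH - pKa)).
    """
    if not 0.0 <= ph <= 14.0:
        raise ValueError("pH must be in [0, 14]")
    p = p or SpeciationParams()
    return 1.0 / (1.0 + 10.0 ** (ph - p.pka))


def ph_profile_peak(km_vmax_by_ph: pd.DataFrame) -> dict[str, object]:
    """pH of maximal Vmax over a discrete pH series (no interpolation).

    ``km_vmax_by_ph`` needs columns ``ph`` and ``vmax``.  Ties are all
    reported; a peak at the edge of the measured range or a single-point
    table is flagged.
    """
    df = km_vmax_by_ph.sort_values("ph").reset_index(drop=True)
    if df.shape[0] < 1:
        raise ValueError("empty table")
    flags = []
    if df.shape[0] == 1:
        return {"peak_ph": [float(df.ph[0])], "vmax": float(df.vmax[0]),
                "flags": ["degenerate_single_point"]}
    if df.shape[0] < 3:
        flags.append("fewer_than_3_points")
    vmax = df["vmax"].to_numpy(dtype=float)
    best = vmax.max()
    peaks = df["ph"][vmax == best].astype(float).tolist()
    if len(peaks) > 1:
        flags.append("tied_maximum")
    if df.ph.iloc[0] in peaks or df.ph.iloc[-1] in peaks:
        flags.append("boundary_maximum")
    return {"peak_ph": peaks, "vmax": float(best), "flags": flags}
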