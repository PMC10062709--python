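"""Endpoint analyses: saturation binding, sigmoid IC50 fits, Ki, and Z'.

All binding math here is depletion-aware: predicted signals come from the
exact mass-action equilibrium (:func:`anisokin.model_core.equilibrium_state`)
rather than free≈total approximations, because in the anisotropy assay the
bound probe is a substantial fraction of total probe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .model_core import BindingParameters, equilibrium_state
from .observable import anisotropy_from_states

__all__ = [
    "SaturationFit",
    "SigmoidFit",
    "ZPrimeResult",
    "FitError",
    "NoDisplacementError",
    "fit_saturation",
    "fit_sigmoid",
    "ki_from_ic50_depletion",
    "cheng_prusoff_ki",
    "z_prime",
    "weighted_mean_sd",
]


class FitError(RuntimeError):
    pass


class NoDisplacementError(FitError):
    """Competition curve is flat: the response window is within the noise."""


# ---------------------------------------------------------------------------
# Saturation binding

@dataclass
class SaturationFit:
    """Global depletion-corrected fit of a two-probe-concentration
    saturation dataset (total + non-specific wells over a BBV dilution
    series)."""

    estimates: dict
    se: dict
    K_NS: float            # fixed non-specific equilibrium constant, nM
    residual_sd: float
    n_points: int
    predicted: np.ndarray
    residuals: np.ndarray

    @property
    def params(self) -> BindingParameters:
        e = self.estimates
        return BindingParameters(
            kon_L=1e-4, Kd_L=e["Kd_L"], kon_NS=1e-5, koff_NS=1e-5 * self.K_NS,
            R_stock=e["R_stock"], NBV_stock=e["NBV_stock"],
            FA_free=e["FA_free"], FA_bound=e["FA_bound"], FA_ns=e["FA_ns"])


_SAT_NAMES = ("Kd_L", "R_stock", "NBV_stock", "FA_free", "FA_bound", "FA_ns")
_SAT_LOG = ("Kd_L", "R_stock", "NBV_stock")


def _sat_predict(theta: np.ndarray, dil, probe, is_total, K_NS) -> np.ndarray:
    Kd, R_stock, NBV_stock = 10.0 ** theta[:3]
    FA_free, FA_bound, FA_ns = theta[3:]
    p = BindingParameters(kon_L=1e-4, Kd_L=Kd, kon_NS=1e-5, koff_NS=1e-5 * K_NS,
                          R_stock=R_stock, NBV_stock=NBV_stock,
                          FA_free=FA_free, FA_bound=FA_bound, FA_ns=FA_ns)
    out = np.empty(len(dil))
    for i, (d, L, tot) in enumerate(zip(dil, probe, is_total)):
        # non-specific wells carry excess unlabeled blocker: receptor silenced
        st = equilibrium_state(p, L_tot=L, R_tot=d * R_stock if tot else 0.0,
                               NBV_tot=d * NBV_stock)
        out[i] = anisotropy_from_states(st, p)
    return out


def fit_saturation(dataset, K_NS: float = 40.0, p0: dict | None = None) -> SaturationFit:
    """Estimate Kd, stock concentrations and intrinsic anisotropies from a
    saturation dataset.

    ``dataset`` is a DataFrame with columns ``bbv_dilution``, ``probe_nM``,
    ``condition`` (total|nonspecific) and ``FA``; both probe concentrations
    share one parameter set (a single global fit over all curves).  Predicted
    anisotropies are computed through the exact equilibrium with full ligand
    depletion.  ``R_stock``/``NBV_stock`` refer to the undiluted stock.

    The non-specific equilibrium constant ``K_NS`` (nM) is held fixed: at
    equilibrium only the ratio NBV/K_NS is identifiable, so the site
    concentration absorbs it.
    """
    d = np.asarray(dataset["bbv_dilution"], dtype=float)
    L = np.asarray(dataset["probe_nM"], dtype=float)
    cond = np.asarray(dataset["condition"])
    fa = np.asarray(dataset["FA"], dtype=float)
    is_total = cond == "total"

    if len(np.unique(d)) < 4:
        raise ValueError("need >= 4 distinct BBV dilutions")
    if not is_total.any():
        raise FitError("no total-binding wells: FA_bound is unidentifiable")
    if is_total.all():
        raise FitError("no non-specific wells: FA_free/FA_ns are unidentifiable")

    fa_lo, fa_hi = fa.min(), fa.max()
    if fa_hi - fa_lo < 1e-12:
        raise FitError("no signal window in the dataset")
    guess = {
        "Kd_L": np.min(L), "R_stock": 2.0 * np.max(L) / np.max(d),
        "NBV_stock": 10.0 * np.max(L) / np.max(d),
        "FA_free": fa_lo, "FA_bound": fa_hi + 0.05,
        "FA_ns": 0.5 * (fa_lo + fa_hi),
    }
    if p0:
        guess.update(p0)
    theta0 = np.array([math.log10(guess[k]) if k in _SAT_LOG else guess[k]
                       for k in _SAT_NAMES])

    def resid(theta):
        try:
            return _sat_predict(theta, d, L, is_total, K_NS) - fa
        except (ValueError, RuntimeError):
            return np.full(len(fa), 1e3)

    # anisotropies bounded by the physical plausibility window
    lb = np.array([-4, -3, -3, -0.2, -0.2, -0.2])
    ub = np.array([4, 4, 4, 0.5, 0.5, 0.5])
    sol = optimize.least_squares(resid, np.clip(theta0, lb, ub), bounds=(lb, ub),
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    dof = max(len(fa) - len(theta0), 1)
    s2 = float(np.sum(sol.fun ** 2) / dof)
    J = sol.jac
    JtJ = J.T @ J
    if np.linalg.cond(JtJ) > 1e12:
        raise FitError(
            "saturation curves carry no curvature (receptor never limiting); "
            "widen the BBV dilution range")
    cov = np.linalg.inv(JtJ) * s2
    se_theta = np.sqrt(np.clip(np.diag(cov), 0, None))

    estimates, se = {}, {}
    for i, name in enumerate(_SAT_NAMES):
        if name in _SAT_LOG:
            estimates[name] = 10.0 ** sol.x[i]
            se[name] = estimates[name] * math.log(10) * se_theta[i]  # delta method
        else:
            estimates[name] = float(sol.x[i])
            se[name] = float(se_theta[i])
    return SaturationFit(estimates=estimates, se=se, K_NS=K_NS,
                         residual_sd=math.sqrt(s2), n_points=len(fa),
                         predicted=fa + sol.fun, residuals=sol.fun)


# ---------------------------------------------------------------------------
# Sigmoid dose-response

@dataclass
class SigmoidFit:
    """Log(inhibitor)-vs-response fit; Hill slope fixed to 1 for the
    three-parameter variant."""

    top: float
    bottom: float
    log_ic50: float      # log10 nM
    hill: float
    se: dict
    variant: str
    residual_sd: float

    @property
    def ic50(self) -> float:
        return 10.0 ** self.log_ic50

    def predict(self, conc_nM) -> np.ndarray:
        c = np.asarray(conc_nM, dtype=float)
        out = np.full(c.shape, self.top, dtype=float)
        pos = c > 0
        out[pos] = self.bottom + (self.top - self.bottom) / (
            1.0 + 10.0 ** ((np.log10(c[pos]) - self.log_ic50) * self.hill))
        return out


def fit_sigmoid(conc_nM, response, variant: str = "three_param") -> SigmoidFit:
    """Fit a monotone-decreasing logistic dose-response curve.

    ``response = bottom + (top - bottom) / (1 + 10^((log c - LogIC50) * h))``
    with ``h = 1`` for ``three_param`` and ``h`` free for ``four_param``.
    Zero-concentration points enter as unconstrained anchors of the top
    plateau (the model evaluates to ``top`` exactly at c = 0).
    """
    c = np.asarray(conc_nM, dtype=float)
    y = np.asarray(response, dtype=float)
    if len(c) != len(y):
        raise ValueError("conc/response length mismatch")
    pos = c > 0
    if pos.sum() < (3 if variant == "three_param" else 4):
        raise ValueError("too few non-zero concentrations for a sigmoid fit")
    if variant not in ("three_param", "four_param"):
        raise ValueError(f"unknown variant {variant!r}")
    logc = np.where(pos, np.log10(np.where(pos, c, 1.0)), -np.inf)

    def model(theta):
        top, bottom, lic50 = theta[:3]
        h = theta[3] if len(theta) == 4 else 1.0
        out = np.full(len(c), top)
        out[pos] = bottom + (top - bottom) / (1 + 10.0 ** ((logc[pos] - lic50) * h))
        return out

    top0 = y[~pos].mean() if (~pos).any() else y[np.argmin(c)]
    bot0 = y[np.argmax(c)]
    lic0 = float(np.median(logc[pos]))
    theta0 = [top0, bot0, lic0] + ([1.0] if variant == "four_param" else [])

    def resid(theta):
        return model(theta) - y

    lb = [-0.5, -0.5, -12.0] + ([0.05] if variant == "four_param" else [])
    ub = [1.5, 1.5, 12.0] + ([10.0] if variant == "four_param" else [])
    sol = optimize.least_squares(resid, theta0, bounds=(lb, ub),
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    dof = max(len(y) - len(theta0), 1)
    s2 = float(np.sum(sol.fun ** 2) / dof)
    sd = math.sqrt(s2)
    top, bottom, lic50 = sol.x[:3]
    if abs(top - bottom) < max(3 * sd, 1e-10):
        raise NoDisplacementError(
            f"response window {abs(top - bottom):.4g} < 3x residual SD {sd:.4g}")
    JtJ = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(JtJ) * s2
        se_vec = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_vec = np.full(len(sol.x), np.nan)
    names = ["top", "bottom", "log_ic50"] + (["hill"] if variant == "four_param" else [])
    se = dict(zip(names, (float(v) for v in se_vec)))
    return SigmoidFit(top=float(top), bottom=float(bottom), log_ic50=float(lic50),
                      hill=float(sol.x[3]) if variant == "four_param" else 1.0,
                      se=se, variant=variant, residual_sd=sd)


# ---------------------------------------------------------------------------
# IC50 -> Ki

def ki_from_ic50_depletion(log_ic50: float, Kd_L: float, L_tot: float,
                           R_tot: float) -> float:
    """Depletion-corrected Ki from a fitted Log(IC50).

    Solves for the competitor equilibrium constant at which the exact
    mass-action equilibrium with competitor total = IC50 yields exactly half
    the specific (receptor-bound) probe of the competitor-free equilibrium.
    Converges to the Cheng-Prusoff value as R_tot -> 0.
    """
    ic50 = 10.0 ** log_ic50
    if not (Kd_L > 0 and L_tot > 0 and R_tot > 0 and math.isfinite(ic50)):
        raise ValueError("Kd_L, L_tot, R_tot and IC50 must be positive")
    base = BindingParameters(kon_L=1e-4, Kd_L=Kd_L)
    rl0 = equilibrium_state(base, L_tot=L_tot, R_tot=R_tot).RL

    def half_excess(log_ki: float) -> float:
        p = base.replace(kon_C=1e-4, Ki_C=10.0 ** log_ki)
        rl = equilibrium_state(p, L_tot=L_tot, R_tot=R_tot, C_tot=ic50).RL
        return rl - 0.5 * rl0

    lo, hi = -12.0, 12.0
    if half_excess(lo) > 0:
        raise FitError(
            f"IC50 = {ic50:.4g} nM is below the depletion floor: even an "
            "infinitely potent competitor cannot halve the specific signal")
    if half_excess(hi) < 0:
        raise FitError("no consistent Ki: signal already halved at Ki = 1e12 nM")
    log_ki = optimize.brentq(half_excess, lo, hi, xtol=1e-12, rtol=8.9e-16)
    return 10.0 ** log_ki


def cheng_prusoff_ki(ic50: float, L: float, Kd: float) -> float:
    """Classical (no-depletion) Ki = IC50 / (1 + [L]/Kd)."""
    if ic50 <= 0 or L < 0 or Kd <= 0:
        raise ValueError("IC50 and Kd must be positive, [L] non-negative")
    return ic50 / (1.0 + L / Kd)


# ---------------------------------------------------------------------------
# HTS quality

@dataclass(frozen=True)
class ZPrimeResult:
    mu_pos: float
    mu_neg: float
    sigma_pos: float
    sigma_neg: float
    z_prime: float


def z_prime(positive, negative) -> ZPrimeResult:
    """Z' = 1 - 3(sigma_pos + sigma_neg)/|mu_pos - mu_neg| with sample SDs."""
    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need >= 2 replicates per control")
    mu_p, mu_n = float(pos.mean()), float(neg.mean())
    if mu_p == mu_n:
        raise ValueError("controls have equal means: Z' undefined")
    s_p, s_n = float(pos.std(ddof=1)), float(neg.std(ddof=1))
    z = 1.0 - 3.0 * (s_p + s_n) / abs(mu_p - mu_n)
    return ZPrimeResult(mu_pos=mu_p, mu_neg=mu_n, sigma_pos=s_p, sigma_neg=s_n,
                        z_prime=z)


def normalize_competition_response(conc_nM, response):
    """Display normalization: competitor-free mean -> 100%, highest
    concentration mean -> 0%.  Presentation only; fitting uses raw FA."""
    c = np.asarray(conc_nM, dtype=float)
    y = np.asarray(response, dtype=float)
    top = y[c == 0].mean() if (c == 0).any() else y[np.argmin(c)]
    bottom = y[c == c.max()].mean()
    if top == bottom:
        raise ValueError("no response window to normalize")
    return 100.0 * (y - bottom) / (top - bottom)


def weighted_mean_sd(values, ses):
    """Inverse-variance weighted mean and weighted SD across experiments."""
    v = np.asarray(values, dtype=float)
    w = 1.0 / np.asarray(ses, dtype=float) ** 2
    mean = float(np.sum(w * v) / np.sum(w))
    var = float(np.sum(w * (v - mean) ** 2) / np.sum(w))
    return mean, math.sqrt(var)
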