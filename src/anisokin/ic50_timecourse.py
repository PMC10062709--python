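"""Log(IC50) as a function of incubation time, and its stabilization fit.

Before a competition assay reaches equilibrium the apparent IC50 drifts:
if the competitor equilibrates faster than the probe, Log(IC50) rises with
time; a competitor slower than the probe produces the inverted, falling
time course; kinetically matched ligands give a flat one.  The approach to
the equilibrium plateau is summarized by a single-phase exponential decay

    Log(IC50)(t) = (Log(IC50)_0 - Log(IC50)_eq) * exp(-k t) + Log(IC50)_eq

whose half-life ln(2)/k measures how long the assay needs before endpoint
readouts are trustworthy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .model_core import BindingParameters, simulate_system
from .observable import anisotropy_from_states
from .equilibrium_analysis import FitError, fit_sigmoid
from .kinetic_global_fit import KineticDataset
from .synthetic_data import ExperimentDesign, build_protocol

__all__ = [
    "IC50TimeCourse",
    "IC50DecayFit",
    "StabilizationError",
    "theoretical_ic50_timecourse",
    "observed_ic50_timecourse",
    "fit_ic50_decay",
]


class StabilizationError(RuntimeError):
    """The exponential stabilization model cannot be fit (k <= 0 or no data)."""


@dataclass
class IC50TimeCourse:
    """Per-timepoint Log(IC50) (log10 nM) with SEs; failed fits are NaN."""

    times: np.ndarray
    log_ic50: np.ndarray
    se: np.ndarray
    source: str                      # "observed" | "theoretical"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.log_ic50)

    @property
    def n_failed(self) -> int:
        return int((~self.valid).sum())


@dataclass
class IC50DecayFit:
    log_ic50_t0: float
    log_ic50_eq: float
    k_per_min: float
    se: dict

    @property
    def half_life_min(self) -> float:
        return math.log(2) / self.k_per_min

    def predict(self, t_min) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        return ((self.log_ic50_t0 - self.log_ic50_eq) * np.exp(-self.k_per_min * t)
                + self.log_ic50_eq)


def _per_time_logic50(times, conc, fa_matrix, source):
    """Three-parameter sigmoid across concentrations at every time point."""
    n = len(times)
    lic = np.full(n, np.nan)
    se = np.full(n, np.nan)
    for i in range(n):
        try:
            fit = fit_sigmoid(conc, fa_matrix[:, i], variant="three_param")
        except (FitError, ValueError):
            continue
        lic[i] = fit.log_ic50
        se[i] = fit.se.get("log_ic50", np.nan)
    return IC50TimeCourse(times=np.asarray(times, dtype=float), log_ic50=lic,
                          se=se, source=source)


def theoretical_ic50_timecourse(params: BindingParameters,
                                design: ExperimentDesign,
                                skip_zero_time: bool = True) -> IC50TimeCourse:
    """Model-predicted Log(IC50)(t) for a competition design.

    Simulates the probe's anisotropy at every competitor concentration of the
    design, then fits the three-parameter sigmoid across concentrations at
    each simulation time point.  Times where the sigmoid fit fails (e.g. the
    grid does not span the transition yet) are flagged NaN, never
    interpolated.  ``params`` must carry the competitor's kinetics
    (``kon_C``, ``Ki_C``).
    """
    if design.kind != "competition_kinetic":
        raise ValueError("theoretical time course needs a competition design")
    conc = np.asarray(design.competitor_nM, dtype=float)
    if (conc > 0).sum() < 6 or (np.log10(conc[conc > 0].max() / conc[conc > 0].min())
                                < 3):
        raise ValueError("competitor grid must have >= 6 concentrations over "
                         ">= 3 decades")
    probe = design.probe_nM[0]
    d = design.bbv_dilutions[0]
    fa = np.empty((len(conc), len(design.times)))
    for i, c in enumerate(conc):
        proto = build_protocol(design, "total", probe, d, c)
        fa[i] = anisotropy_from_states(simulate_system(params, proto), params)
    times = design.times
    tc = _per_time_logic50(times, conc, fa, "theoretical")
    if skip_zero_time and times[0] == 0.0:
        # at t = 0 nothing is bound yet; no displacement is measurable
        tc.log_ic50[0] = np.nan
        tc.se[0] = np.nan
    return tc


def observed_ic50_timecourse(dataset: KineticDataset,
                             competitor_of=None) -> IC50TimeCourse:
    """Per-timepoint sigmoid fits on measured competition traces.

    Every trace must share one time grid; traces are keyed by their
    competitor concentration via ``competitor_of(trace) -> nM`` (defaults to
    ``trace.competitor_nM`` attribute lookup).  Duplicate concentrations are
    averaged; time points with an incomplete concentration series are skipped
    with a warning.
    """
    if competitor_of is None:
        competitor_of = lambda tr: tr.competitor_nM  # noqa: E731
    times = dataset.traces[0].protocol.times
    groups: dict[float, list] = {}
    for tr in dataset.traces:
        if len(tr.protocol.times) != len(times) or np.any(tr.protocol.times != times):
            warnings.warn(f"trace {tr.well} has a different time grid: skipped")
            continue
        groups.setdefault(float(competitor_of(tr)), []).append(tr.fa)
    conc = np.array(sorted(groups))
    fa = np.stack([np.mean(groups[c], axis=0) for c in conc])
    tc = _per_time_logic50(times, conc, fa, "observed")
    if times[0] == 0.0:
        tc.log_ic50[0] = np.nan
        tc.se[0] = np.nan
    return tc


def fit_ic50_decay(tc: IC50TimeCourse, weighted: bool = True) -> IC50DecayFit:
    """Fit the single-phase exponential stabilization model to a time course.

    Weighted least squares with per-point SE weights by default.  Time zero
    is the reaction-initiating (BBV-addition) event; times are converted to
    minutes so the rate is reported in 1/min and the half-life in minutes.

    Raises
    ------
    StabilizationError
        With fewer than 4 valid time points, on non-convergence, or when the
        optimum has k <= 0 (no stabilization detectable).
    """
    ok = tc.valid
    if ok.sum() < 4:
        raise StabilizationError(f"need >= 4 valid time points, have {int(ok.sum())}")
    t_min = tc.times[ok] / 60.0
    y = tc.log_ic50[ok]
    sigma = tc.se[ok] if (weighted and np.all(np.isfinite(tc.se[ok]))
                          and np.all(tc.se[ok] > 0)) else None

    def model(t, y0, yeq, k):
        return (y0 - yeq) * np.exp(-k * t) + yeq

    span = max(t_min[-1] - t_min[0], 1e-9)
    p0 = (y[0], y[-1], 3.0 / span)
    try:
        popt, pcov = curve_fit(model, t_min, y, p0=p0, sigma=sigma,
                               absolute_sigma=sigma is not None,
                               bounds=([-12, -12, 1e-9], [12, 12, np.inf]),
                               maxfev=20000)
    except RuntimeError as exc:
        raise StabilizationError(f"stabilization fit did not converge: {exc}") from exc
    y0, yeq, k = popt
    if not (k > 0) or abs(y0 - yeq) < 1e-12:
        raise StabilizationError("no stabilization detected (k <= 0 or flat course)")
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    se = {"log_ic50_t0": float(perr[0]), "log_ic50_eq": float(perr[1]),
          "k_per_min": float(perr[2]),
          "half_life_min": float(math.log(2) / k ** 2 * perr[2])}
    return IC50DecayFit(log_ic50_t0=float(y0), log_ic50_eq=float(yeq),
                        k_per_min=float(k), se=se)
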