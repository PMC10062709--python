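"""Global estimation of binding parameters from multi-well kinetic FA data.

The loss is the (optionally time-weighted) mean-squared error between
measured anisotropy and the anisotropy predicted by simulating every well's
protocol under one shared parameter set.  Optimization uses a Nelder-Mead
simplex embedded in a simulated-annealing temperature ladder: at each
temperature, simplex searches are restarted from Metropolis-perturbed points
(perturbation magnitude proportional to temperature on the log-parameter
scale) and accepted by the Metropolis criterion on the loss; the default
schedule starts at temperature 1000 with 10^3 loss evaluations per
temperature and a reduction factor of 0.2 down to 0.1, followed by a plain
simplex polish.  Runs are deterministic given the seed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy import optimize
from scipy.integrate import odeint

from .model_core import (SPECIES, AssayProtocol, BindingParameters,
                         SimulationError)

__all__ = [
    "KineticTrace",
    "KineticDataset",
    "FitConfig",
    "GlobalFitResult",
    "kinetic_loss",
    "time_weights",
    "fit_global",
    "select_competition_points",
    "predict_dataset",
    "dataset_from_plate",
]

_IDX = {name: i for i, name in enumerate(SPECIES)}

log = logging.getLogger(__name__)

#: Parameters optimized on log10 scale (positivity enforced structurally);
#: intrinsic anisotropies stay on the linear scale.
LOG_PARAMS = ("kon_L", "Kd_L", "kon_C", "Ki_C", "kon_NS", "koff_NS",
              "R_stock", "NBV_stock")
LINEAR_PARAMS = ("FA_free", "FA_bound", "FA_ns")

DEFAULT_BOUNDS = {
    **{k: (1e-8, 1e2) for k in ("kon_L", "kon_C", "kon_NS", "koff_NS")},
    **{k: (1e-8, 1e4) for k in ("Kd_L", "Ki_C")},
    **{k: (1e-3, 1e4) for k in ("R_stock", "NBV_stock")},
    # intrinsic anisotropy cannot exceed the single-photon photoselection
    # limit (~0.4); the bounds mirror the plausibility window used on data
    **{k: (-0.2, 0.5) for k in LINEAR_PARAMS},
}


@dataclass(frozen=True)
class KineticTrace:
    """One well's anisotropy time course plus the protocol that produced it."""

    well: str
    fa: np.ndarray
    protocol: AssayProtocol
    include: np.ndarray | None = None  # boolean point mask (None = all)
    role: str = "total"
    probe_nM: float = 0.0
    competitor_nM: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "fa", np.asarray(self.fa, dtype=float))
        if len(self.fa) != len(self.protocol.times):
            raise ValueError(f"trace {self.well}: FA/time length mismatch")
        if self.include is not None:
            inc = np.asarray(self.include, dtype=bool)
            if len(inc) != len(self.fa):
                raise ValueError(f"trace {self.well}: mask length mismatch")
            object.__setattr__(self, "include", inc)


@dataclass(frozen=True)
class KineticDataset:
    traces: tuple
    experiment_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "traces", tuple(self.traces))
        if not self.traces:
            raise ValueError("dataset has no traces")


@dataclass
class FitConfig:
    """Annealing schedule, weighting and parameter-space configuration."""

    start_temp: float = 1000.0
    iters_per_temp: int = 1000
    reduction: float = 0.2
    stop_temp: float = 0.1
    weight_scheme: str = "less_timescaling"   # or "uniform"
    weight_tau: float = 600.0                 # s
    seed: int = 0
    free: tuple = ("kon_L", "Kd_L", "R_stock", "FA_free", "FA_bound")
    bounds: dict = field(default_factory=dict)
    n_uncertainty: int = 25       # perturbed refits used for the SE spread
    nm_maxfev: int = 1000         # budget of one simplex restart
    perturb_scale: float = 1.0    # log10 units at the start temperature

    def __post_init__(self):
        if not (0 < self.reduction < 1):
            raise ValueError("reduction factor must be in (0, 1)")
        if not (self.stop_temp < self.start_temp):
            raise ValueError("stop temperature must be below start temperature")
        if not self.free:
            raise ValueError("at least one free parameter required")
        for name in self.free:
            if name not in LOG_PARAMS + LINEAR_PARAMS:
                raise ValueError(f"unknown parameter {name!r}")

    def bound(self, name):
        return self.bounds.get(name, DEFAULT_BOUNDS[name])


@dataclass
class GlobalFitResult:
    params: BindingParameters
    estimates: dict
    se: dict
    loss: float
    per_trace_rms: dict
    convergence: list          # (temperature, best loss) pairs
    n_evals: int
    seed: int


# ---------------------------------------------------------------------------
# Time weighting

def time_weights(times, scheme: str = "less_timescaling", tau: float = 600.0):
    """Positive, non-increasing weights over time, normalized to mean 1.

    ``less_timescaling`` down-weights late points as ``1/(1 + t/tau)`` so
    that the rapidly changing early part of a kinetic trace dominates the
    loss; times are measured from the reaction-initiating event and clipped
    at zero.
    """
    t = np.clip(np.asarray(times, dtype=float), 0.0, None)
    if scheme == "uniform":
        w = np.ones(len(t))
    elif scheme == "less_timescaling":
        w = 1.0 / (1.0 + t / tau)
    else:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    return w / w.mean()


# ---------------------------------------------------------------------------
# Fast stacked simulation: wells sharing one time grid and event schedule are
# integrated as a single block-diagonal ODE system (banded Jacobian), which
# removes almost all per-well integrator overhead inside the optimizer loop.

@njit(cache=False)
def _stack_rhs(y, t, kon_L, koff_L, kon_C, koff_C, kon_NS, koff_NS, W):
    out = np.empty(7 * W)
    for w in range(W):
        b = 7 * w
        R, L, C, NBV = y[b], y[b + 1], y[b + 2], y[b + 3]
        RL, RC, NBVL = y[b + 4], y[b + 5], y[b + 6]
        v1 = kon_L * R * L - koff_L * RL
        v2 = kon_C * R * C - koff_C * RC
        v3 = kon_NS * NBV * L - koff_NS * NBVL
        out[b] = -v1 - v2
        out[b + 1] = -v1 - v3
        out[b + 2] = -v2
        out[b + 3] = -v3
        out[b + 4] = v1
        out[b + 5] = v2
        out[b + 6] = v3
    return out


@njit(cache=False)
def _stack_jac_banded(y, t, kon_L, koff_L, kon_C, koff_C, kon_NS, koff_NS, W):
    # packed banded storage with ml = mu = 6: packed[6 + i - j, 7w + j] = J[i, j]
    packed = np.zeros((13, 7 * W))
    for w in range(W):
        b = 7 * w
        R, L, C, NBV = y[b], y[b + 1], y[b + 2], y[b + 3]
        J = np.zeros((7, 7))
        a1, b1 = kon_L * L, kon_L * R
        J[0, 0] -= a1; J[0, 1] -= b1; J[0, 4] += koff_L
        J[1, 0] -= a1; J[1, 1] -= b1; J[1, 4] += koff_L
        J[4, 0] += a1; J[4, 1] += b1; J[4, 4] -= koff_L
        a2, b2 = kon_C * C, kon_C * R
        J[0, 0] -= a2; J[0, 2] -= b2; J[0, 5] += koff_C
        J[2, 0] -= a2; J[2, 2] -= b2; J[2, 5] += koff_C
        J[5, 0] += a2; J[5, 2] += b2; J[5, 5] -= koff_C
        a3, b3 = kon_NS * L, kon_NS * NBV
        J[3, 3] -= b3; J[3, 1] -= a3; J[3, 6] += koff_NS
        J[1, 3] -= b3; J[1, 1] -= a3; J[1, 6] += koff_NS
        J[6, 3] += b3; J[6, 1] += a3; J[6, 6] -= koff_NS
        for i in range(7):
            for j in range(7):
                packed[6 + i - j, b + j] = J[i, j]
    return packed


def _simulate_stacked(params: BindingParameters, y0_stack: np.ndarray,
                      times: np.ndarray, events) -> np.ndarray:
    """Integrate W wells at once; returns concentrations (W, n_times, 7).

    Mirrors :func:`anisokin.model_core.simulate_system`: integration restarts
    at each event, samples at an event time are pre-event, tolerances are the
    same.
    """
    W = y0_stack.shape[0]
    args = (params.kon_L, params.koff_L, params.kon_C, params.koff_C,
            params.kon_NS, params.koff_NS, W)
    y = y0_stack.ravel().copy()
    out = np.empty((len(times), W * 7))
    t_cursor = min(0.0, times[0])
    boundaries = [ev.time_s for ev in events] + [times[-1]]
    evs = list(events) + [None]
    n_done = 0
    for ev, t_end in zip(evs, boundaries):
        hi = int(np.searchsorted(times, t_end, side="right"))
        seg_times = times[n_done:hi]
        grid = np.concatenate(([t_cursor], seg_times, [t_end]))
        keep = np.concatenate(([True], np.diff(grid) > 0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol, info = odeint(_stack_rhs, y, grid[keep], args=args,
                               Dfun=_stack_jac_banded, ml=6, mu=6,
                               rtol=1e-8, atol=1e-10, full_output=True,
                               mxstep=10000)
        if info["message"] != "Integration successful.":
            raise SimulationError(f"stacked integration failed: {info['message'].strip()}")
        np.clip(sol, 0.0, None, out=sol)
        full = np.empty((len(grid), W * 7))
        full[keep] = sol
        full[~keep] = sol[np.maximum(np.cumsum(keep) - 1, 0)[~keep]]
        if len(seg_times):
            out[n_done:hi] = full[1:1 + len(seg_times)]
            n_done = hi
        y = full[-1].copy()
        if ev is not None:
            y *= ev.dilution_factor
            y.reshape(W, 7)[:, _IDX[ev.species]] += ev.increment_nM
        t_cursor = t_end
    return out.reshape(len(times), W, 7).transpose(1, 0, 2)


def _group_traces(traces):
    """Group trace indices by (time grid, event schedule) for stacking."""
    groups: dict[tuple, list[int]] = {}
    for i, tr in enumerate(traces):
        key = (tr.protocol.times.tobytes(),
               tuple((ev.time_s, ev.species, ev.increment_nM, ev.dilution_factor)
                     for ev in tr.protocol.events))
        groups.setdefault(key, []).append(i)
    return list(groups.values())


class _Predictor:
    """Caches trace grouping; evaluates predicted FA for all traces."""

    def __init__(self, dataset: KineticDataset):
        self.traces = dataset.traces
        self.groups = _group_traces(self.traces)

    def __call__(self, params: BindingParameters):
        preds = [None] * len(self.traces)
        for idx in self.groups:
            trs = [self.traces[i] for i in idx]
            y0 = np.stack([t.protocol.initial_state(params) for t in trs])
            conc = _simulate_stacked(params, y0, trs[0].protocol.times,
                                     trs[0].protocol.events)
            L, RL, NBVL = conc[:, :, 1], conc[:, :, 4], conc[:, :, 6]
            tot = L + RL + NBVL
            with np.errstate(invalid="ignore", divide="ignore"):
                fa = (L * params.FA_free + RL * params.FA_bound
                      + NBVL * params.FA_ns) / tot
            for k, i in enumerate(idx):
                preds[i] = fa[k]
        return preds


def predict_dataset(params: BindingParameters, dataset: KineticDataset):
    """Predicted FA arrays for every trace (same order as ``dataset.traces``)."""
    return _Predictor(dataset)(params)


# ---------------------------------------------------------------------------
# Loss

def kinetic_loss(params: BindingParameters, dataset: KineticDataset,
                 weight_scheme: str = "less_timescaling",
                 weight_tau: float = 600.0,
                 _predictor=None) -> float:
    """Weighted mean-squared error of predicted vs measured anisotropy.

    Averages ``w * (FA_pred - FA_obs)^2`` over every included (trace, time)
    point.  Simulation failure returns ``+inf`` (with a warning) so an
    optimizer can step over pathological parameter sets.
    """
    predictor = _predictor or _Predictor(dataset)
    try:
        preds = predictor(params)
    except SimulationError as exc:
        warnings.warn(f"simulation failed during loss evaluation: {exc}")
        return math.inf
    num = 0.0
    n = 0
    for tr, pred in zip(dataset.traces, preds):
        w = time_weights(tr.protocol.times, weight_scheme, weight_tau)
        r2 = w * (pred - tr.fa) ** 2
        if tr.include is not None:
            r2 = r2[tr.include]
        if not np.all(np.isfinite(r2)):
            return math.inf
        num += float(r2.sum())
        n += len(r2)
    return num / n


# ---------------------------------------------------------------------------
# Annealed simplex fit

def _encode(params: BindingParameters, free):
    return np.array([math.log10(getattr(params, k)) if k in LOG_PARAMS
                     else getattr(params, k) for k in free])


def _decode(x, params0: BindingParameters, free):
    changes = {k: (10.0 ** v if k in LOG_PARAMS else float(v))
               for k, v in zip(free, x)}
    return params0.replace(**changes)


def fit_global(dataset: KineticDataset, config: FitConfig,
               params0: BindingParameters) -> GlobalFitResult:
    """Simulated-annealing global fit of the free parameters.

    ``params0`` supplies starting values for the free parameters and fixed
    values for everything else.  The run is bit-reproducible given
    ``config.seed``.  Parameter uncertainty is the spread of
    ``config.n_uncertainty`` simplex refits on parametric-bootstrap
    replicates of the dataset (predictions re-noised at the fitted
    per-trace residual level).
    """
    rng = np.random.default_rng(config.seed)
    free = tuple(config.free)
    lo = np.array([math.log10(config.bound(k)[0]) if k in LOG_PARAMS
                   else config.bound(k)[0] for k in free])
    hi = np.array([math.log10(config.bound(k)[1]) if k in LOG_PARAMS
                   else config.bound(k)[1] for k in free])
    predictor = _Predictor(dataset)
    n_evals = 0

    def loss_of(x):
        nonlocal n_evals
        n_evals += 1
        if np.any(x < lo) or np.any(x > hi):
            excess = float(np.sum(np.maximum(lo - x, 0) + np.maximum(x - hi, 0)))
            return 1e6 * (1.0 + excess)
        return kinetic_loss(_decode(x, params0, free), dataset,
                            config.weight_scheme, config.weight_tau,
                            _predictor=predictor)

    x_cur = np.clip(_encode(params0, free), lo, hi)
    f_cur = loss_of(x_cur)
    if not math.isfinite(f_cur):
        raise RuntimeError("starting parameters are not simulatable")
    x_best, f_best = x_cur.copy(), f_cur

    convergence = []
    T = config.start_temp
    while T >= config.stop_temp:
        budget = config.iters_per_temp
        sigma = config.perturb_scale * T / config.start_temp
        # Metropolis scale: at the start temperature moves costing ~the best
        # loss are acceptable; near the stop temperature only improvements are
        tau_T = max(f_best, 1e-300) * T / config.start_temp
        while budget > 0:
            x_start = np.clip(x_cur + rng.normal(size=len(free)) * sigma, lo, hi)
            res = optimize.minimize(
                loss_of, x_start, method="Nelder-Mead",
                options={"maxfev": min(config.nm_maxfev, budget),
                         "xatol": 1e-7, "fatol": 1e-13})
            budget -= res.nfev
            delta = res.fun - f_cur
            accept = delta < 0 or rng.random() < math.exp(-delta / tau_T)
            log.debug("T=%.3g restart loss=%.6g (current %.6g) -> %s",
                      T, res.fun, f_cur, "accepted" if accept else "rejected")
            if accept:
                x_cur, f_cur = res.x, res.fun
            if res.fun < f_best:
                x_best, f_best = res.x.copy(), res.fun
        convergence.append((T, f_best))
        # cool around the incumbent optimum
        x_cur, f_cur = x_best.copy(), f_best
        T *= config.reduction

    polish = optimize.minimize(loss_of, x_best, method="Nelder-Mead",
                               options={"maxfev": 400 * len(free),
                                        "xatol": 1e-9, "fatol": 1e-14})
    if polish.fun <= f_best:
        x_best, f_best = polish.x, polish.fun

    # uncertainty: spread of refits on parametric-bootstrap datasets (data
    # re-noised at the per-trace fitted residual level), started from the
    # optimum — measures how much the data constrain each free parameter
    params_best = _decode(x_best, params0, free)
    refit_x = []
    if config.n_uncertainty:
        preds_best = predictor(params_best)
        resid_sd = [float(np.sqrt(np.mean((p - tr.fa) ** 2)))
                    for tr, p in zip(dataset.traces, preds_best)]
        for _ in range(config.n_uncertainty):
            boot = KineticDataset(traces=tuple(
                KineticTrace(tr.well,
                             p + sd * rng.standard_normal(len(tr.fa)),
                             tr.protocol, tr.include, tr.role, tr.probe_nM,
                             tr.competitor_nM)
                for tr, p, sd in zip(dataset.traces, preds_best, resid_sd)))
            boot_predictor = _Predictor(boot)

            def boot_loss(x, _b=boot, _bp=boot_predictor):
                if np.any(x < lo) or np.any(x > hi):
                    return 1e6
                return kinetic_loss(_decode(x, params0, free), _b,
                                    config.weight_scheme, config.weight_tau,
                                    _predictor=_bp)

            r = optimize.minimize(boot_loss, x_best, method="Nelder-Mead",
                                  options={"maxfev": 150 * len(free),
                                           "xatol": 1e-6, "fatol": 1e-13})
            refit_x.append(r.x)
    estimates = {k: getattr(params_best, k) for k in free}
    if refit_x:
        nat = np.array([[getattr(_decode(x, params0, free), k) for k in free]
                        for x in refit_x])
        se = {k: float(nat[:, i].std(ddof=1)) if len(refit_x) > 1 else 0.0
              for i, k in enumerate(free)}
    else:
        se = {k: float("nan") for k in free}

    preds = predictor(params_best)
    per_trace_rms = {tr.well: float(np.sqrt(np.mean((p - tr.fa) ** 2)))
                     for tr, p in zip(dataset.traces, preds)}
    return GlobalFitResult(params=params_best, estimates=estimates, se=se,
                           loss=float(f_best), per_trace_rms=per_trace_rms,
                           convergence=convergence, n_evals=n_evals,
                           seed=config.seed)


# ---------------------------------------------------------------------------
# Plate table -> kinetic dataset

def dataset_from_plate(plate, well_map, design, experiment_id: str = ""):
    """Blank-correct a raw plate table and assemble a :class:`KineticDataset`.

    Each measurement well becomes one :class:`KineticTrace`; the well's assay
    protocol is reconstructed from the design and its well-map metadata.
    Traces carry ``competitor_nM`` metadata for downstream grouping.
    """
    from .observable import (anisotropy_from_intensities, blank_correct,
                             pivot_channels)
    from .synthetic_data import build_protocol

    corrected = blank_correct(plate, well_map)
    wide = pivot_channels(corrected)
    meta = well_map.set_index("well")
    traces = []
    for well, sub in wide.groupby("well", sort=False):
        sub = sub.sort_values("time_s")
        row = meta.loc[well]
        fa = anisotropy_from_intensities(sub["I_par"].to_numpy(),
                                         sub["I_perp"].to_numpy(), warn=False)
        proto = build_protocol(design, row["role"], float(row["probe_nM"]),
                               float(row["bbv_dilution"]) or 1.0,
                               float(row["competitor_nM"]))
        traces.append(KineticTrace(well=well, fa=fa, protocol=proto,
                                   role=row["role"],
                                   probe_nM=float(row["probe_nM"]),
                                   competitor_nM=float(row["competitor_nM"])))
    return KineticDataset(traces=tuple(traces), experiment_id=experiment_id)


# ---------------------------------------------------------------------------
# Concentration-point selection for competitor-kinetics fitting

def select_competition_points(conc_nM, response, sigmoid_fit) -> np.ndarray:
    """Boolean inclusion mask: slope points plus two flanking plateau points.

    A point is on the slope when the *fitted* response at its concentration
    lies between 10% and 90% of the fitted window; on each side the two
    plateau points closest to the slope are retained.  Plateau points far
    from the slope carry little competitor-kinetics information, so dropping
    them concentrates weight on the informative region.  The mask is
    invariant to the ordering of the input concentrations.  With fewer than
    4 slope points all points are retained (with a warning).
    """
    c = np.asarray(conc_nM, dtype=float)
    predicted = sigmoid_fit.predict(c)
    top, bottom = sigmoid_fit.top, sigmoid_fit.bottom
    frac = (top - predicted) / (top - bottom)  # 0 at top plateau, 1 at bottom
    on_slope = (frac >= 0.10) & (frac <= 0.90)
    if on_slope.sum() < 4:
        warnings.warn("fewer than 4 slope points: retaining all concentration points")
        return np.ones(len(c), dtype=bool)
    mask = on_slope.copy()
    order = np.argsort(c, kind="stable")
    for side in (order, order[::-1]):   # ascending: top plateau first; then bottom
        first_slope = next(k for k, i in enumerate(side) if on_slope[i])
        near = [i for k, i in enumerate(side) if not on_slope[i] and k < first_slope]
        for i in near[-2:]:
            mask[i] = True
    return mask
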