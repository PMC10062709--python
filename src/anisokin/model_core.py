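"""One-site receptor binding reaction system and its simulation.

The model describes a fluorescent probe ``L`` binding a receptor ``R``
displayed on budded-baculovirus (BBV) particles, an unlabeled competitor
``C`` binding the same site, and non-specific association of the probe with
particle sites ``NBV``::

    R + L   <-> RL      kon_L / koff_L
    R + C   <-> RC      kon_C / koff_C
    NBV + L <-> NBVL    kon_NS / koff_NS

All concentrations are nM, times are seconds, association rates 1/(nM*s)
and dissociation rates 1/s.  Because the assay runs under ligand depletion
(bound probe is a large fraction of total probe), free concentrations are
never approximated by totals: the full mass-action system is integrated as
an ODE, and equilibria are solved exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import odeint
from scipy.optimize import brentq

__all__ = [
    "SPECIES",
    "BindingParameters",
    "SystemState",
    "AdditionEvent",
    "AssayProtocol",
    "Trajectory",
    "SimulationError",
    "simulate_system",
    "equilibrium_state",
]

#: Species order used throughout: free receptor, free probe, free competitor,
#: free non-specific sites, and the three complexes.
SPECIES = ("R", "L", "C", "NBV", "RL", "RC", "NBVL")

_IDX = {name: i for i, name in enumerate(SPECIES)}


class SimulationError(RuntimeError):
    """Raised when the ODE integrator fails or produces unphysical output."""


@dataclass(frozen=True)
class BindingParameters:
    """Rate, affinity, stock-concentration and anisotropy parameters.

    Affinities are carried as (kon, Kd) pairs with koff derived
    (``koff = kon * Kd``), matching how plate-assay fits are usually
    parameterized; optimizers work on log10 of the positive parameters.

    Parameters
    ----------
    kon_L, Kd_L
        Probe association rate (1/(nM*s)) and equilibrium dissociation
        constant (nM).
    kon_C, Ki_C
        Competitor association rate and equilibrium constant. ``kon_C = 0``
        renders the competitor inert.
    kon_NS, koff_NS
        Non-specific binding of the probe to particle sites.  ``kon_NS = 0``
        disables non-specific binding.
    R_stock, NBV_stock
        Receptor and non-specific-site concentrations of the *undiluted*
        particle stock (nM); wells see ``stock * dilution``.
    FA_free, FA_bound, FA_ns
        Intrinsic anisotropies of the free, receptor-bound and
        non-specifically bound probe.
    """

    kon_L: float
    Kd_L: float
    kon_C: float = 0.0
    Ki_C: float = 1.0
    kon_NS: float = 0.0
    koff_NS: float = 1.0
    R_stock: float = 1.0
    NBV_stock: float = 0.0
    FA_free: float = 0.08
    FA_bound: float = 0.30
    FA_ns: float = 0.15

    def __post_init__(self) -> None:
        if not (self.kon_L > 0 and self.Kd_L > 0):
            raise ValueError("kon_L and Kd_L must be positive")
        if self.kon_C < 0 or self.kon_NS < 0:
            raise ValueError("association rates must be non-negative")
        if self.kon_C > 0 and not self.Ki_C > 0:
            raise ValueError("Ki_C must be positive when kon_C > 0")
        if self.kon_NS > 0 and not self.koff_NS > 0:
            raise ValueError("koff_NS must be positive when kon_NS > 0")
        if self.R_stock < 0 or self.NBV_stock < 0:
            raise ValueError("stock concentrations must be non-negative")
        for name in ("FA_free", "FA_bound", "FA_ns"):
            fa = getattr(self, name)
            if not (-0.5 < fa <= 1.0):
                raise ValueError(f"{name}={fa} outside the anisotropy range (-0.5, 1.0]")
        for name in ("koff_L", "koff_C"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"derived {name} is not finite")

    @property
    def koff_L(self) -> float:
        return self.kon_L * self.Kd_L

    @property
    def koff_C(self) -> float:
        return self.kon_C * self.Ki_C

    @property
    def K_NS(self) -> float:
        """Non-specific equilibrium constant koff_NS/kon_NS (inf if disabled)."""
        return self.koff_NS / self.kon_NS if self.kon_NS > 0 else math.inf

    def replace(self, **changes) -> "BindingParameters":
        return replace(self, **changes)


@dataclass(frozen=True)
class SystemState:
    """Instantaneous concentrations (nM) of the seven species."""

    R: float
    L: float
    C: float
    NBV: float
    RL: float
    RC: float
    NBVL: float

    def __post_init__(self) -> None:
        for name in SPECIES:
            v = getattr(self, name)
            if v < -1e-9:
                raise ValueError(f"negative concentration {name}={v}")

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SystemState":
        return cls(*(float(v) for v in y))

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @property
    def L_total(self) -> float:
        return self.L + self.RL + self.NBVL

    @property
    def R_total(self) -> float:
        return self.R + self.RL + self.RC

    @property
    def C_total(self) -> float:
        return self.C + self.RC


@dataclass(frozen=True)
class AdditionEvent:
    """Instantaneous reagent addition.

    ``dilution_factor`` rescales *all* concentrations at the event (1.0 means
    the added volume is neglected); ``increment_nM`` is then added to the free
    pool of ``species``.
    """

    time_s: float
    species: str
    increment_nM: float
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.increment_nM < 0:
            raise ValueError("increment must be >= 0")
        if not (0 < self.dilution_factor <= 1):
            raise ValueError("dilution factor must be in (0, 1]")


@dataclass(frozen=True)
class AssayProtocol:
    """Initial well composition, timed additions, and measurement grid.

    ``initial`` maps free-species names to starting totals (complexes start at
    zero: reagents are mixed unbound).  ``dilution`` is the BBV stock dilution
    of the well; helper :meth:`initial_state` applies it to ``R_stock`` and
    ``NBV_stock``.
    """

    initial: dict = field(default_factory=dict)
    dilution: float = 1.0
    events: tuple = ()
    times: np.ndarray = field(default_factory=lambda: np.array([0.0]))

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.times.ndim != 1 or len(self.times) == 0:
            raise ValueError("measurement grid must be a non-empty 1-D array")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("measurement times must be strictly increasing")
        if not (0 < self.dilution <= 1):
            raise ValueError("dilution must be in (0, 1]")
        for s in self.initial:
            if s not in SPECIES:
                raise ValueError(f"unknown species {s!r} in initial composition")
        horizon = self.times[-1]
        prev = -math.inf
        for ev in self.events:
            if not isinstance(ev, AdditionEvent):
                raise TypeError("events must be AdditionEvent instances")
            if ev.time_s <= prev:
                raise ValueError("event times must be strictly increasing")
            if ev.time_s > horizon:
                raise ValueError("event outside the simulation horizon")
            prev = ev.time_s

    def initial_state(self, params: BindingParameters) -> np.ndarray:
        y0 = np.zeros(len(SPECIES))
        y0[_IDX["R"]] = self.dilution * params.R_stock
        y0[_IDX["NBV"]] = self.dilution * params.NBV_stock
        for s, c in self.initial.items():
            y0[_IDX[s]] = c  # explicit initial overrides the stock-derived value
        return y0


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered solution of the reaction system on a measurement grid."""

    times: np.ndarray
    concentrations: np.ndarray  # shape (n_times, 7), columns ordered as SPECIES

    def __len__(self) -> int:
        return len(self.times)

    def __getitem__(self, i: int) -> SystemState:
        return SystemState.from_array(self.concentrations[i])

    def __iter__(self):
        for row in self.concentrations:
            yield SystemState.from_array(row)

    def species(self, name: str) -> np.ndarray:
        return self.concentrations[:, _IDX[name]]


def _rhs(y, t, kon_L, koff_L, kon_C, koff_C, kon_NS, koff_NS):
    R, L, C, NBV, RL, RC, NBVL = y
    v1 = kon_L * R * L - koff_L * RL
    v2 = kon_C * R * C - koff_C * RC
    v3 = kon_NS * NBV * L - koff_NS * NBVL
    return (-v1 - v2, -v1 - v3, -v2, -v3, v1, v2, v3)


def _jac(y, t, kon_L, koff_L, kon_C, koff_C, kon_NS, koff_NS):
    R, L, C, NBV = y[0], y[1], y[2], y[3]
    J = np.zeros((7, 7))
    # d v1 / d(R, L, RL)
    a, b = kon_L * L, kon_L * R
    J[0, 0] -= a; J[0, 1] -= b; J[0, 4] += koff_L
    J[1, 0] -= a; J[1, 1] -= b; J[1, 4] += koff_L
    J[4, 0] += a; J[4, 1] += b; J[4, 4] -= koff_L
    # d v2 / d(R, C, RC)
    a, b = kon_C * C, kon_C * R
    J[0, 0] -= a; J[0, 2] -= b; J[0, 5] += koff_C
    J[2, 0] -= a; J[2, 2] -= b; J[2, 5] += koff_C
    J[5, 0] += a; J[5, 2] += b; J[5, 5] -= koff_C
    # d v3 / d(NBV, L, NBVL)
    a, b = kon_NS * L, kon_NS * NBV
    J[3, 3] -= b; J[3, 1] -= a; J[3, 6] += koff_NS
    J[1, 3] -= b; J[1, 1] -= a; J[1, 6] += koff_NS
    J[6, 3] += b; J[6, 1] += a; J[6, 6] -= koff_NS
    return J


#: Integrator tolerances: stiff-capable LSODA, restarted at each addition event.
RTOL = 1e-8
ATOL = 1e-10  # nM
_NEG_TOL = 1e-6  # nM; worst negative excursion tolerated before erroring


def _integrate_segment(y0, t_grid, rate_args):
    """LSODA integration over ``t_grid`` (first entry is the start time)."""
    if len(t_grid) == 1:
        return y0[None, :].copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol, info = odeint(
            _rhs, y0, t_grid, args=rate_args, Dfun=_jac,
            rtol=RTOL, atol=ATOL, full_output=True, mxstep=10000,
        )
    if info["message"] != "Integration successful.":
        raise SimulationError(
            f"ODE integration failed ({info['message'].strip()}) "
            f"for rates {rate_args}"
        )
    if sol.min() < -_NEG_TOL:
        raise SimulationError(
            f"negative concentration {sol.min():.3e} nM beyond tolerance "
            f"for rates {rate_args}"
        )
    np.clip(sol, 0.0, None, out=sol)
    return sol


def simulate_system(params: BindingParameters, protocol: AssayProtocol) -> Trajectory:
    """Integrate the mass-action ODE system over the protocol's time grid.

    Integration restarts at every addition event (the concentration step is a
    discontinuity).  A measurement coinciding exactly with an event time is
    reported *pre*-event.  Mass balance between events is conserved to within
    the integrator tolerance.

    Raises
    ------
    SimulationError
        On integrator failure or a negative concentration beyond tolerance;
        the message names the offending rate set.
    """
    rate_args = (params.kon_L, params.koff_L, params.kon_C, params.koff_C,
                 params.kon_NS, params.koff_NS)
    times = protocol.times
    y = protocol.initial_state(params)
    out = np.empty((len(times), len(SPECIES)))

    t_cursor = min(0.0, times[0])
    boundaries = [ev.time_s for ev in protocol.events] + [times[-1]]
    events = list(protocol.events) + [None]
    n_done = 0
    for ev, t_end in zip(events, boundaries):
        # measurement times inside (t_cursor, t_end]; event-time samples are pre-event
        sel = slice(n_done, int(np.searchsorted(times, t_end, side="right")))
        seg_times = times[sel]
        grid = np.concatenate(([t_cursor], seg_times, [t_end]))
        # guard against duplicate knots when samples touch the boundaries
        keep = np.concatenate(([True], np.diff(grid) > 0))
        sol = _integrate_segment(y, grid[keep], rate_args)
        full = np.empty((len(grid), len(SPECIES)))
        full[keep] = sol
        full[~keep] = sol[np.maximum(np.cumsum(keep) - 1, 0)[~keep]]
        if len(seg_times):
            out[sel] = full[1:1 + len(seg_times)]
            n_done += len(seg_times)
        y = full[-1].copy()
        if ev is not None:
            y *= ev.dilution_factor
            y[_IDX[ev.species]] += ev.increment_nM
        t_cursor = t_end
    return Trajectory(times=times.copy(), concentrations=out)


def _free_receptor(L: float, C_tot: float, R_tot: float, Kd: float, Ki: float) -> float:
    """Free R at fixed free L, solving the coupled R/C balance exactly.

    Eliminating C = C_tot / (1 + R/Ki) from R's balance gives a quadratic in
    R with a single positive root.
    """
    a = 1.0 + L / Kd
    if not math.isfinite(Ki):  # inert competitor
        return R_tot / a
    b = a * Ki + C_tot - R_tot
    c = -R_tot * Ki
    # a > 0, c <= 0: the positive root, in a cancellation-safe form
    disc = math.sqrt(b * b - 4 * a * c)
    return (2 * -c) / (b + disc) if b >= 0 else (-b + disc) / (2 * a)


def equilibrium_state(
    params: BindingParameters,
    L_tot: float = 0.0,
    R_tot: float = 0.0,
    C_tot: float = 0.0,
    NBV_tot: float = 0.0,
) -> SystemState:
    """Exact steady state of the three-reaction system at given totals.

    Reduces the coupled mass-action equilibria to a single monotone equation
    in free probe concentration, bracketed on [0, L_tot] and solved with
    Brent's method; the R/C sub-system is eliminated in closed form.  Each
    equilibrium relation holds to < 1e-10 relative at the returned state.
    """
    for name, v in (("L_tot", L_tot), ("R_tot", R_tot),
                    ("C_tot", C_tot), ("NBV_tot", NBV_tot)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    Kd, Ki = params.Kd_L, params.Ki_C if params.kon_C > 0 else math.inf
    Kns = params.K_NS
    if Kns == 0 and NBV_tot > 0:
        raise ValueError("irreversible non-specific binding has no finite equilibrium")

    def free_nbv(L: float) -> float:
        return NBV_tot / (1.0 + L / Kns) if math.isfinite(Kns) else NBV_tot

    def residual(L: float) -> float:
        R = _free_receptor(L, C_tot, R_tot, Kd, Ki)
        NBV = free_nbv(L)
        ns = NBV / Kns if math.isfinite(Kns) else 0.0
        return L * (1.0 + R / Kd + ns) - L_tot

    if L_tot == 0:
        L = 0.0
    else:
        lo, hi = 0.0, L_tot
        if residual(hi) < 0:  # numerically impossible, but keep the contract honest
            raise RuntimeError(f"equilibrium bracketing failed, residual(L_tot)={residual(hi)}")
        L = brentq(residual, lo, hi, xtol=1e-300, rtol=1e-15, maxiter=200)
    R = _free_receptor(L, C_tot, R_tot, Kd, Ki)
    NBV = free_nbv(L)
    C = C_tot / (1.0 + R / Ki) if math.isfinite(Ki) else C_tot
    RL = R * L / Kd
    RC = R * C / Ki if math.isfinite(Ki) else 0.0
    NBVL = NBV * L / Kns if math.isfinite(Kns) else 0.0

    scale = max(L_tot, R_tot, C_tot, NBV_tot, 1e-30)
    res = (abs(L + RL + NBVL - L_tot), abs(R + RL + RC - R_tot),
           abs(C + RC - C_tot), abs(NBV + NBVL - NBV_tot))
    if max(res) > 1e-10 * scale:
        raise RuntimeError(f"equilibrium solver did not converge, residuals={res}")
    return SystemState(R=R, L=L, C=C, NBV=NBV, RL=RL, RC=RC, NBVL=NBVL)
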