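"""Synthetic 384-well fluorescence-anisotropy experiments.

Generates complete raw datasets — per-well polarized intensity traces, the
well map, and the ground-truth parameter record — for the three assay
designs the package analyzes:

* ``saturation_kinetic``: probe at two concentrations against a two-fold
  BBV dilution series, total and non-specific wells, 90 min association
  followed by an excess-competitor chase, sampled every 5 min.
* ``saturation_endpoint``: the same plate read at a single equilibrium
  endpoint.
* ``competition_kinetic``: fixed probe and BBV, a competitor dilution
  series (plus a competitor-free well), sampled every 5 min for 5 h.

Wells are filled row-major on a 384-well plate (rows A-P, columns 1-24),
with each BBV dilution's blank placed adjacent to its measurement wells and
recorded explicitly in the well map.  Intensities are built by inverting the
anisotropy equation at a brightness proportional to the probe concentration,
adding a BBV-scaled blank baseline on both channels (autofluorescence /
scatter surrogate), and applying multiplicative Gaussian channel noise.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .model_core import (AdditionEvent, AssayProtocol, BindingParameters,
                         simulate_system)
from .observable import anisotropy_from_states, intensities_from_anisotropy

__all__ = [
    "ExperimentDesign",
    "NoiseModel",
    "serial_dilution",
    "generate_experiment",
    "generate_controls_plate",
    "saturation_kinetic_design",
    "competition_kinetic_design",
    "DEFAULT_TRUE_PARAMS",
    "SPIPERONE_KON",
    "SPIPERONE_KI",
]

_ROWS = "ABCDEFGHIJKLMNOP"
PLATE_CAPACITY = 384

#: Fast, high-affinity unlabeled blocker used for non-specific wells and the
#: dissociation chase (spiperone-like kinetics).
SPIPERONE_KON = 1e-5   # 1/(nM*s): at 50-333 uM this blocks receptors in seconds
SPIPERONE_KI = 0.1     # nM

#: Ground truth used by the recovery benchmarks: the probe's globally fitted
#: kinetic parameter set (kon 4.2e-4 1/(nM*s), koff 2.8e-4 1/s, stock 20 nM,
#: free-probe anisotropy 0.081), with non-specific binding tuned so that
#: roughly 8% of the probe is non-specifically bound at the standard 1/30
#: BBV dilution.
DEFAULT_TRUE_PARAMS = BindingParameters(
    kon_L=4.2e-4, Kd_L=2.8e-4 / 4.2e-4,
    kon_C=SPIPERONE_KON, Ki_C=SPIPERONE_KI,
    kon_NS=1e-5, koff_NS=4e-4,
    R_stock=20.0, NBV_stock=100.0,
    FA_free=0.081, FA_bound=0.35, FA_ns=0.15,
)


def serial_dilution(start: float, factor: float, n: int) -> np.ndarray:
    """Geometric dilution series ``start * factor**i`` for i = 0..n-1."""
    if start <= 0:
        raise ValueError("start concentration must be positive")
    if not (0 < factor < 1):
        raise ValueError("dilution factor must be in (0, 1)")
    if n < 1:
        raise ValueError("need at least one concentration")
    return start * factor ** np.arange(n)


@dataclass(frozen=True)
class ExperimentDesign:
    kind: str                                  # saturation_kinetic | saturation_endpoint | competition_kinetic
    probe_nM: tuple = (0.5, 3.0)
    bbv_dilutions: tuple = tuple(serial_dilution(1 / 30, 0.5, 4))
    competitor_name: str = ""
    competitor_nM: tuple = ()                  # includes 0 for the anchor well
    ns_block_nM: float = 50_000.0              # unlabeled blocker in non-specific wells
    chase_time_s: float | None = 5400.0        # excess-competitor chase (None = no chase)
    chase_nM: float = 333_000.0
    interval_s: float = 300.0
    horizon_s: float = 12_600.0
    replicates: int = 1
    include_free_ligand: bool = True

    def __post_init__(self):
        if self.kind not in ("saturation_kinetic", "saturation_endpoint",
                             "competition_kinetic"):
            raise ValueError(f"unknown design kind {self.kind!r}")
        for d in self.bbv_dilutions:
            if not (0 < d < 1):
                raise ValueError("BBV dilutions must be in (0, 1)")
        if self.chase_time_s is not None and self.chase_time_s >= self.horizon_s:
            raise ValueError("chase must precede the measurement horizon")

    @property
    def times(self) -> np.ndarray:
        return np.arange(0.0, self.horizon_s + 0.5 * self.interval_s,
                         self.interval_s)


@dataclass(frozen=True)
class NoiseModel:
    """Channel noise, BBV-scaled blank baseline, and probe brightness."""

    rel_sd: float = 0.01                # multiplicative Gaussian SD per channel
    blank_per_dilution: float = 9000.0  # a.u. per channel per unit BBV dilution
    brightness: float = 3000.0          # total intensity (I_par + 2*I_perp) per nM probe
    seed: int = 0

    def __post_init__(self):
        if self.rel_sd < 0 or self.blank_per_dilution < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if self.brightness <= 0:
            raise ValueError("brightness must be positive")


def saturation_kinetic_design(**overrides) -> ExperimentDesign:
    """The standard saturation-kinetics plate: 0.5 and 3 nM probe, two-fold
    BBV dilutions, 90 min association then a 333 uM blocker chase."""
    return ExperimentDesign(kind="saturation_kinetic", **overrides)


def competition_kinetic_design(competitor_name: str, competitor_nM,
                               probe_nM: float = 0.5,
                               bbv_dilution: float = 1 / 30,
                               horizon_s: float = 18_000.0,
                               **overrides) -> ExperimentDesign:
    """Competition plate: fixed probe and BBV, competitor series + zero well,
    5-min sampling for 5 h."""
    conc = tuple(float(c) for c in competitor_nM)
    if 0.0 not in conc:
        conc = (0.0,) + conc
    return ExperimentDesign(kind="competition_kinetic", probe_nM=(probe_nM,),
                            bbv_dilutions=(bbv_dilution,),
                            competitor_name=competitor_name, competitor_nM=conc,
                            chase_time_s=None, horizon_s=horizon_s, **overrides)


def _well_name(i: int) -> str:
    return f"{_ROWS[i // 24]}{i % 24 + 1}"


def build_protocol(design: ExperimentDesign, role: str, probe: float,
                   dilution: float, competitor: float = 0.0) -> AssayProtocol:
    """Assay protocol of one well: reagents pre-mixed, reaction initiated at
    t = 0 by the BBV addition, optional chase event."""
    initial = {"L": probe}
    if role == "nonspecific":
        initial["C"] = design.ns_block_nM
    elif competitor > 0:
        initial["C"] = competitor
    if role == "free-ligand":
        initial["R"] = 0.0
        initial["NBV"] = 0.0
        dilution = 1.0
    events = ()
    if design.chase_time_s is not None:
        events = (AdditionEvent(design.chase_time_s, "C", design.chase_nM),)
    return AssayProtocol(initial=initial, dilution=dilution, events=events,
                         times=design.times)


def _design_wells(design: ExperimentDesign):
    """Yield (role, probe_nM, competitor_nM, bbv_dilution) per measurement well."""
    wells = []
    for _ in range(design.replicates):
        if design.kind in ("saturation_kinetic", "saturation_endpoint"):
            for probe in design.probe_nM:
                for d in design.bbv_dilutions:
                    wells.append(("total", probe, 0.0, d))
                    wells.append(("nonspecific", probe, design.ns_block_nM, d))
                if design.include_free_ligand:
                    wells.append(("free-ligand", probe, 0.0, 0.0))
        else:
            probe = design.probe_nM[0]
            d = design.bbv_dilutions[0]
            for c in design.competitor_nM:
                wells.append(("total", probe, c, d))
    return wells


def generate_experiment(design: ExperimentDesign, params: BindingParameters,
                        noise: NoiseModel):
    """Simulate a full plate; returns ``(plate, well_map, truth)``.

    ``plate`` is the long-format intensity table, ``well_map`` the matching
    metadata table (including one blank per BBV dilution, and a buffer blank
    for free-ligand wells), and ``truth`` a JSON-serializable record of the
    generating parameters, design and noise model.  Deterministic per seed.
    """
    rng = np.random.default_rng(noise.seed)
    wells = _design_wells(design)
    dilutions_used = sorted({w[3] for w in wells})
    n_wells = len(wells) + len(dilutions_used)
    if n_wells > PLATE_CAPACITY:
        raise ValueError(f"design needs {n_wells} wells > {PLATE_CAPACITY}")

    times = design.times
    map_rows, plate_rows = [], []
    idx = 0

    def emit(well, par, perp):
        for t, ip, iq in zip(times, par, perp):
            plate_rows.append((well, t, "par", ip))
            plate_rows.append((well, t, "perp", iq))

    for dilution in dilutions_used:
        group = [w for w in wells if w[3] == dilution]
        baseline = noise.blank_per_dilution * dilution
        # blank first, adjacent to its dilution's measurement wells
        blank_well = _well_name(idx); idx += 1
        map_rows.append((blank_well, "blank", 0.0, design.competitor_name, 0.0, dilution))
        for ch in range(2):
            noise_f = 1.0 + noise.rel_sd * rng.standard_normal(len(times))
            emit_vals = baseline * noise_f
            for t, v in zip(times, emit_vals):
                plate_rows.append((blank_well, t, "par" if ch == 0 else "perp", v))
        for role, probe, comp, d in group:
            well = _well_name(idx); idx += 1
            comp_name = design.competitor_name if (
                design.kind == "competition_kinetic" and comp > 0) else (
                "blocker" if comp > 0 else "")
            map_rows.append((well, role, probe, comp_name, comp, d))
            proto = build_protocol(design, role, probe, d, comp)
            traj = simulate_system(params, proto)
            fa = np.asarray(anisotropy_from_states(traj, params))
            i_total = noise.brightness * probe
            par, perp = intensities_from_anisotropy(fa, np.full(len(times), i_total))
            par = (par + baseline) * (1.0 + noise.rel_sd * rng.standard_normal(len(times)))
            perp = (perp + baseline) * (1.0 + noise.rel_sd * rng.standard_normal(len(times)))
            emit(well, par, perp)

    plate = pd.DataFrame(plate_rows, columns=["well", "time_s", "channel", "intensity"])
    well_map = pd.DataFrame(map_rows, columns=["well", "role", "probe_nM",
                                               "competitor_name", "competitor_nM",
                                               "bbv_dilution"])
    truth = {
        "params": {k: getattr(params, k) for k in (
            "kon_L", "Kd_L", "kon_C", "Ki_C", "kon_NS", "koff_NS",
            "R_stock", "NBV_stock", "FA_free", "FA_bound", "FA_ns")},
        "derived": {"koff_L": params.koff_L, "koff_C": params.koff_C},
        "design": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(design).items()},
        "noise": asdict(noise),
    }
    return plate, well_map, truth


def generate_controls_plate(n_pos: int, n_neg: int, delta_fa: float = 0.12,
                            sd: float = 0.0058, mu_neg: float = 0.08,
                            seed: int = 0):
    """Gaussian positive/negative control replicates for Z' estimation.

    The window ``delta_fa`` defaults to the assay's total-vs-nonspecific
    anisotropy difference of 0.12; the per-control SD is a free knob.
    """
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need >= 2 replicates per control")
    rng = np.random.default_rng(seed)
    pos = mu_neg + delta_fa + sd * rng.standard_normal(n_pos)
    neg = mu_neg + sd * rng.standard_normal(n_neg)
    return pos, neg
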