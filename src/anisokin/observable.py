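"""Anisotropy observation model and plate-reader I/O.

Fluorescence anisotropy is computed from blank-corrected polarized
intensities as ``FA = (I_par - I_perp) / (I_par + 2*I_perp)``; the predicted
anisotropy of a reaction mixture is the concentration-weighted mean of the
intrinsic anisotropies of the probe's binding states (free, receptor-bound,
non-specifically bound).  Channels are assumed pre-calibrated (instrument
G-factor of 1).

Plate data travel as a long-format CSV (columns ``well, time_s, channel,
intensity`` with ``channel`` in {par, perp}) plus a well map CSV (``well,
role, probe_nM, competitor_name, competitor_nM, bbv_dilution`` with ``role``
in {total, nonspecific, blank, free-ligand}).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .model_core import BindingParameters, SystemState, Trajectory

__all__ = [
    "anisotropy_from_intensities",
    "intensities_from_anisotropy",
    "anisotropy_from_states",
    "blank_correct",
    "read_plate_csv",
    "write_plate_csv",
    "read_well_map",
    "write_well_map",
    "pivot_channels",
    "UndefinedAnisotropyError",
    "BlankMatchError",
]

PLATE_COLUMNS = ["well", "time_s", "channel", "intensity"]
WELL_MAP_COLUMNS = ["well", "role", "probe_nM", "competitor_name",
                    "competitor_nM", "bbv_dilution"]
ROLES = ("total", "nonspecific", "blank", "free-ligand")

#: Post-blanking anisotropy outside this window is physically implausible
#: for an organic-dye probe and triggers a warning (never a mutation).
FA_PLAUSIBLE = (-0.2, 0.5)


class UndefinedAnisotropyError(ValueError):
    """Total intensity is zero: anisotropy is undefined for that reading."""


class BlankMatchError(ValueError):
    """A measurement well has no blank with matching BBV dilution."""


def anisotropy_from_intensities(I_par, I_perp, warn: bool = True):
    """FA from parallel/perpendicular intensities.

    Accepts scalars or arrays.  Raises :class:`UndefinedAnisotropyError`
    where ``I_par + 2*I_perp == 0``; values outside the plausibility window
    emit a warning when ``warn`` is true.
    """
    I_par = np.asarray(I_par, dtype=float)
    I_perp = np.asarray(I_perp, dtype=float)
    total = I_par + 2.0 * I_perp
    if np.any(total == 0):
        raise UndefinedAnisotropyError("zero total intensity: FA undefined")
    fa = (I_par - I_perp) / total
    if warn and (np.any(fa < FA_PLAUSIBLE[0]) or np.any(fa > FA_PLAUSIBLE[1])):
        warnings.warn(
            f"anisotropy outside the plausible window {FA_PLAUSIBLE}; "
            "check blank correction", stacklevel=2)
    return fa if fa.ndim else float(fa)


def intensities_from_anisotropy(fa, I_total):
    """Invert the anisotropy equation at a given total intensity I_par + 2*I_perp.

    Round-trips with :func:`anisotropy_from_intensities` to floating precision.
    """
    fa = np.asarray(fa, dtype=float)
    I_total = np.asarray(I_total, dtype=float)
    if np.any(fa <= -0.5) or np.any(fa > 1.0):
        raise ValueError("anisotropy outside (-0.5, 1.0]")
    if np.any(I_total < 0):
        raise ValueError("total intensity must be >= 0")
    I_par = I_total * (1.0 + 2.0 * fa) / 3.0
    I_perp = I_total * (1.0 - fa) / 3.0
    if I_par.ndim:
        return I_par, I_perp
    return float(I_par), float(I_perp)


def anisotropy_from_states(state, params: BindingParameters):
    """Predicted FA of a mixture: concentration-weighted mean over probe states.

    ``state`` is a :class:`SystemState` or a :class:`Trajectory` (vectorized).
    The result is a convex combination of ``FA_free``, ``FA_bound`` and
    ``FA_ns`` weighted by the free, receptor-bound and non-specifically bound
    probe concentrations.
    """
    if isinstance(state, Trajectory):
        L, RL, NBVL = state.species("L"), state.species("RL"), state.species("NBVL")
    else:
        L, RL, NBVL = state.L, state.RL, state.NBVL
    total = np.asarray(L + RL + NBVL, dtype=float)
    if np.any(total <= 0):
        raise ValueError("no probe in the system: FA undefined")
    fa = (L * params.FA_free + RL * params.FA_bound + NBVL * params.FA_ns) / total
    return fa if np.ndim(fa) else float(fa)


def blank_correct(plate: pd.DataFrame, well_map: pd.DataFrame) -> pd.DataFrame:
    """Channel-wise subtraction of the matched blank from every measurement well.

    Blanks are matched on BBV dilution ("the blank wells ... only contained
    the same concentration of BBVs"); subtraction happens per channel and
    per time point, before any anisotropy computation.  The returned table
    has an extra ``blank_well`` column recording which blank corrected each
    well; blank wells themselves are dropped.

    Raises
    ------
    BlankMatchError
        Listing every measurement well without a matched blank.
    """
    meta = well_map.set_index("well")
    blanks = meta[meta["role"] == "blank"]
    blank_by_dilution: dict[float, str] = {}
    for well, row in blanks.iterrows():
        blank_by_dilution.setdefault(row["bbv_dilution"], well)

    measured = meta[meta["role"] != "blank"]
    unmatched = [w for w, row in measured.iterrows()
                 if row["bbv_dilution"] not in blank_by_dilution]
    if unmatched:
        raise BlankMatchError(f"no matched blank for wells: {sorted(unmatched)}")

    blank_tables = {
        w: plate[plate["well"] == w].set_index(["time_s", "channel"])["intensity"]
        for w in set(blank_by_dilution.values())
    }
    parts = []
    for well, row in measured.iterrows():
        bw = blank_by_dilution[row["bbv_dilution"]]
        sub = plate[plate["well"] == well].copy()
        key = pd.MultiIndex.from_frame(sub[["time_s", "channel"]])
        sub["intensity"] = sub["intensity"].to_numpy() - blank_tables[bw].reindex(key).to_numpy()
        if sub["intensity"].isna().any():
            raise BlankMatchError(
                f"blank {bw} lacks readings for some time/channel of well {well}")
        sub["blank_well"] = bw
        parts.append(sub)
    return pd.concat(parts, ignore_index=True)


def pivot_channels(plate: pd.DataFrame) -> pd.DataFrame:
    """Wide per-(well, time) frame with ``I_par``/``I_perp`` columns."""
    wide = plate.pivot_table(index=["well", "time_s"], columns="channel",
                             values="intensity", aggfunc="first").reset_index()
    wide.columns.name = None
    return wide.rename(columns={"par": "I_par", "perp": "I_perp"})


# ---------------------------------------------------------------------------
# CSV I/O.  One canonical dialect: UTF-8, comma, '.' decimal, header row.
# Floats are written with shortest round-trip repr, so read(write(x)) is
# bit-exact.

def write_plate_csv(plate: pd.DataFrame, path) -> None:
    plate[PLATE_COLUMNS].to_csv(path, index=False)


def read_plate_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"well": str, "channel": str},
                     float_precision="round_trip")
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing plate columns {sorted(missing)}")
    bad = set(df["channel"]) - {"par", "perp"}
    if bad:
        raise ValueError(f"{path}: unknown channels {sorted(bad)}")
    return df


def write_well_map(well_map: pd.DataFrame, path) -> None:
    well_map[WELL_MAP_COLUMNS].to_csv(path, index=False)


def read_well_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"well": str, "role": str, "competitor_name": str},
                     float_precision="round_trip")
    missing = set(WELL_MAP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing well-map columns {sorted(missing)}")
    bad = set(df["role"]) - set(ROLES)
    if bad:
        raise ValueError(f"{path}: unknown roles {sorted(bad)}")
    return df
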