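"""From raw OD/GFP kinetics to log induction-factor (ln I) trajectories.

Normalization follows the two-control plate design: blank wells (no yeast,
same compound and concentration) carry the material's optical background in
both channels and are subtracted; expression is GFP per unit biomass,
P(t) = (GFP - GFP_blank) / max(OD - OD_blank, od_floor). The induction
factor of a treated reporter against its vehicle control is
ln I(t) = ln(P_treated(t) / P_vehicle(t)), optionally drift-corrected by
subtracting the housekeeping (PGK1) reporter's ln I under the same
condition. Replicates are combined by averaging ln I pointwise.

Degenerate readings are floored (``p_floor`` on expression, ``od_floor`` on
biomass) rather than propagated; floor event counts are reported and logged.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from pelitox.library_io import HOUSEKEEPING, PlateTimeSeries, ValidationError

logger = logging.getLogger(__name__)

#: floors guarding against division blow-ups on near-zero signals
P_FLOOR = 1e-6
OD_FLOOR = 0.01


@dataclasses.dataclass
class InductionProfile:
    """One reporter's replicate-averaged ln I trajectory for one condition."""

    orf_id: str
    compound: str
    concentration: float
    time_min: np.ndarray
    ln_i: np.ndarray
    replicate_count: int


def normalize_expression(
    plate: PlateTimeSeries,
    od_floor: float = OD_FLOOR,
    p_floor: float = P_FLOOR,
) -> tuple[pd.DataFrame, dict]:
    """Blank-corrected per-well expression P(t) for every yeast-bearing well.

    Returns (P, info): P is wells x time; info counts floored OD denominators
    and floored (nonpositive) expression values.
    """
    layout = plate.layout.frame.set_index("well")
    keys = list(zip(layout["compound"], layout["concentration_mg_L"]))
    key_by_well = pd.Series(keys, index=layout.index)

    is_blank = layout["role"] == "blank_control"
    blank_wells = layout.index[is_blank]
    if not len(blank_wells):
        raise ValidationError("no blank_control wells on the plate")
    blank_od = plate.od.loc[blank_wells].groupby(key_by_well[blank_wells]).mean()
    blank_gfp = plate.gfp.loc[blank_wells].groupby(key_by_well[blank_wells]).mean()

    yeast_wells = layout.index[~is_blank]
    missing = sorted(set(key_by_well[yeast_wells]) - set(blank_od.index))
    if missing:
        raise ValidationError(
            f"no matching blank_control for conditions (compound, mg/L): {missing[:10]}"
        )

    wk = key_by_well[yeast_wells]
    od_corr = plate.od.loc[yeast_wells].to_numpy() - blank_od.loc[wk].to_numpy()
    gfp_corr = plate.gfp.loc[yeast_wells].to_numpy() - blank_gfp.loc[wk].to_numpy()

    od_floored = int((od_corr < od_floor).sum())
    denom = np.maximum(od_corr, od_floor)
    p = gfp_corr / denom
    p_floored = int((p < p_floor).sum())
    p = np.maximum(p, p_floor)
    if od_floored or p_floored:
        logger.warning(
            "normalization floors applied: %d OD points < %g, %d expression points < %g",
            od_floored, od_floor, p_floored, p_floor,
        )
    P = pd.DataFrame(p, index=yeast_wells, columns=plate.od.columns)
    return P, {"od_floored": od_floored, "p_floored": p_floored}


def log_induction(
    treated: np.ndarray, control: np.ndarray, p_floor: float = P_FLOOR
) -> np.ndarray:
    """ln I(t) = ln(P_treated / P_control), both floored at ``p_floor`` first."""
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.shape != control.shape:
        raise ValidationError(
            f"grid mismatch: treated has shape {treated.shape}, control {control.shape}"
        )
    return np.log(np.maximum(treated, p_floor) / np.maximum(control, p_floor))


def clip_for_display(ln_i: np.ndarray, bound: float = 2.0) -> np.ndarray:
    """Clip ln I to [-bound, +bound] for heatmap rendering only.

    Never used for PELI computation.
    """
    return np.clip(np.asarray(ln_i, dtype=float), -bound, bound)


def induction_table(
    plate: PlateTimeSeries,
    drift_correction: bool = True,
    od_floor: float = OD_FLOOR,
    p_floor: float = P_FLOOR,
) -> pd.DataFrame:
    """Replicate-averaged ln I trajectories for every (orf, compound, conc).

    Tidy output columns: ``orf, compound, concentration_mg_L, time_min, ln_i,
    replicate_count``. When ``drift_correction`` is on, the housekeeping
    (PGK1) reporter's ln I under the same condition is subtracted from every
    reporter's ln I of that condition.
    """
    P, _ = normalize_expression(plate, od_floor=od_floor, p_floor=p_floor)
    layout = plate.layout.frame.set_index("well")
    lay = layout.loc[P.index]

    # vehicle-control expression per ORF (replicates averaged)
    veh = lay[lay["role"] == "vehicle_control"]
    if not len(veh):
        raise ValidationError("no vehicle_control wells on the plate")
    ctrl_by_orf = P.loc[veh.index].groupby(veh["orf"]).mean()

    rep = lay[lay["role"] == "reporter"]
    missing_ctrl = sorted(set(rep["orf"]) - set(ctrl_by_orf.index))
    if missing_ctrl:
        raise ValidationError(f"reporter ORFs without vehicle controls: {missing_ctrl[:10]}")

    ln_i = np.log(P.loc[rep.index].to_numpy()) - np.log(
        ctrl_by_orf.loc[rep["orf"]].to_numpy()
    )

    if drift_correction:
        internal = lay[lay["role"] == "internal_control"]
        if not len(internal):
            raise ValidationError("drift correction requested but no internal_control wells")
        ikeys = pd.Series(
            list(zip(internal["compound"], internal["concentration_mg_L"])),
            index=internal.index,
        )
        pgk = P.loc[internal.index].groupby(ikeys).mean()
        veh_key = ("", 0.0)
        if veh_key not in pgk.index:
            raise ValidationError("no internal_control wells at the vehicle condition")
        drift = np.log(pgk.to_numpy()) - np.log(pgk.loc[[veh_key]].to_numpy())
        drift_df = pd.DataFrame(drift, index=pgk.index, columns=P.columns)
        rkeys = list(zip(rep["compound"], rep["concentration_mg_L"]))
        missing_int = sorted(set(rkeys) - set(drift_df.index))
        if missing_int:
            raise ValidationError(
                f"conditions without internal_control wells: {missing_int[:10]}"
            )
        ln_i = ln_i - drift_df.loc[rkeys].to_numpy()

    long = pd.DataFrame(ln_i, index=rep.index, columns=P.columns)
    long = long.assign(
        orf=rep["orf"].to_numpy(),
        compound=rep["compound"].to_numpy(),
        concentration_mg_L=rep["concentration_mg_L"].to_numpy(),
    ).melt(
        id_vars=["orf", "compound", "concentration_mg_L"],
        var_name="time_min",
        value_name="ln_i",
    )
    grouped = (
        long.groupby(["orf", "compound", "concentration_mg_L", "time_min"], sort=True)
        .agg(ln_i=("ln_i", "mean"), replicate_count=("ln_i", "size"))
        .reset_index()
    )
    grouped["time_min"] = grouped["time_min"].astype(float)
    return grouped


def profiles_from_table(table: pd.DataFrame) -> list[InductionProfile]:
    """Split a tidy induction table into per-condition trajectory objects."""
    out = []
    for (orf, compound, conc), grp in table.groupby(
        ["orf", "compound", "concentration_mg_L"], sort=True
    ):
        grp = grp.sort_values("time_min")
        out.append(
            InductionProfile(
                orf_id=orf,
                compound=compound,
                concentration=float(conc),
                time_min=grp["time_min"].to_numpy(dtype=float),
                ln_i=grp["ln_i"].to_numpy(dtype=float),
                replicate_count=int(grp["replicate_count"].iloc[0]),
            )
        )
    return out
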