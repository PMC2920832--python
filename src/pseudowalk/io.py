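"""CSV/JSON readers and writers, schema validation, and the strain-table
reproduction pipeline.

All files are comma-separated UTF-8 with a mandatory header and "." as
the decimal mark.  Writers produce canonical formatting so that
write -> read -> write round-trips are byte-identical.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dispersal import (
    MSDCurve,
    fit_crw,
    ensemble_msd,
    gamma_step,
    step_size,
    turn_angle,
)
from .shape import CellOutline
from .simulate import PseudopodParams, PseudopodEvent, Trajectory

__all__ = [
    "SchemaError",
    "read_events",
    "write_events",
    "read_trajectories",
    "write_trajectories",
    "read_outlines",
    "write_outlines",
    "read_msd",
    "write_msd",
    "read_strain_table",
    "write_strain_table",
    "read_angles",
    "write_angles",
    "events_to_frame",
    "trajectories_to_frame",
    "run_table1_reproduction",
]

logger = logging.getLogger("pseudowalk")

EVENT_COLUMNS = [
    "cell_id", "index", "kind", "side", "alpha_deg",
    "x_start", "y_start", "t_start", "x_end", "y_end", "t_end",
]
TRAJECTORY_COLUMNS = ["cell_id", "step", "x", "y"]
OUTLINE_COLUMNS = ["cell_id", "node_index", "x", "y"]
MSD_COLUMNS = ["lag", "msd", "n_traj"]
STRAIN_COLUMNS = ["strain", "lambda_p", "s", "a", "phi", "sigma_phi"]
ANGLE_COLUMNS = ["angle_deg"]


class SchemaError(ValueError):
    """A file does not conform to its declared column schema."""


def _check_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column '{col}'")


def _check_numeric(df: pd.DataFrame, columns: Sequence[str], path) -> pd.DataFrame:
    df = df.copy()
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise SchemaError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in column "
                f"'{col}' at line {line}"
            )
        df[col] = coerced
    return df


def _read_csv(path) -> pd.DataFrame:
    # round_trip parsing so write -> read -> write is byte-identical
    return pd.read_csv(path, sep=",", encoding="utf-8", float_precision="round_trip")


def read_events(path) -> pd.DataFrame:
    df = _read_csv(path)
    _check_columns(df, EVENT_COLUMNS, path)
    numeric = [c for c in EVENT_COLUMNS if c not in ("kind", "side")]
    return _check_numeric(df, numeric, path)


def write_events(df: pd.DataFrame, path) -> None:
    _check_columns(df, EVENT_COLUMNS, path)
    df.to_csv(path, index=False)


def read_trajectories(path) -> pd.DataFrame:
    df = _read_csv(path)
    _check_columns(df, TRAJECTORY_COLUMNS, path)
    return _check_numeric(df, TRAJECTORY_COLUMNS, path)


def write_trajectories(df: pd.DataFrame, path) -> None:
    _check_columns(df, TRAJECTORY_COLUMNS, path)
    df.to_csv(path, index=False)


def read_outlines(path) -> List[Tuple[int, CellOutline]]:
    """Read outlines (implicitly closed polygons) grouped by cell_id."""
    df = _read_csv(path)
    _check_columns(df, OUTLINE_COLUMNS, path)
    df = _check_numeric(df, OUTLINE_COLUMNS, path)
    outlines = []
    for cell_id, group in df.groupby("cell_id", sort=True):
        group = group.sort_values("node_index")
        outlines.append((int(cell_id), CellOutline(group[["x", "y"]].to_numpy())))
    return outlines


def write_outlines(outlines: Sequence[Tuple[int, CellOutline]], path) -> None:
    rows = []
    for cell_id, outline in outlines:
        for i, (x, y) in enumerate(outline.vertices):
            rows.append((cell_id, i, x, y))
    pd.DataFrame(rows, columns=OUTLINE_COLUMNS).to_csv(path, index=False)


def read_msd(path) -> MSDCurve:
    df = _read_csv(path)
    _check_columns(df, MSD_COLUMNS, path)
    df = _check_numeric(df, MSD_COLUMNS, path)
    return MSDCurve(
        lags=df["lag"].to_numpy(float),
        msd=df["msd"].to_numpy(float),
        n_traj=int(df["n_traj"].iloc[0]),
    )


def write_msd(curve: MSDCurve, path) -> None:
    pd.DataFrame(
        {"lag": curve.lags, "msd": curve.msd, "n_traj": curve.n_traj}
    ).to_csv(path, index=False)


def read_strain_table(path) -> pd.DataFrame:
    df = _read_csv(path)
    _check_columns(df, STRAIN_COLUMNS, path)
    numeric = [c for c in STRAIN_COLUMNS if c != "strain"]
    if "gamma_obs" in df.columns:
        numeric = numeric + ["gamma_obs"]
    df = _check_numeric(df, numeric, path)
    if df["strain"].duplicated().any():
        dup = df["strain"][df["strain"].duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicate strain name {dup!r}")
    return df


def write_strain_table(df: pd.DataFrame, path) -> None:
    _check_columns(df, STRAIN_COLUMNS, path)
    df.to_csv(path, index=False)


def read_angles(path) -> np.ndarray:
    df = _read_csv(path)
    _check_columns(df, ANGLE_COLUMNS, path)
    df = _check_numeric(df, ANGLE_COLUMNS, path)
    return df["angle_deg"].to_numpy(float)


def write_angles(angles, path) -> None:
    pd.DataFrame({"angle_deg": np.asarray(angles, float)}).to_csv(path, index=False)


def events_to_frame(events: Sequence[PseudopodEvent], cell_id: int = 0) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (cell_id, e.index, e.kind, e.side, e.alpha,
             e.x_start, e.y_start, e.t_start, e.x_end, e.y_end, e.t_end)
            for e in events
        ],
        columns=EVENT_COLUMNS,
    )


def trajectories_to_frame(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    rows = []
    for cell_id, traj in enumerate(trajectories):
        for step, (x, y) in enumerate(traj.positions):
            rows.append((cell_id, step, x, y))
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)


def params_from_row(row) -> PseudopodParams:
    return PseudopodParams(
        lambda_p=float(row["lambda_p"]),
        s=float(row["s"]),
        a=float(row["a"]),
        phi=float(row["phi"]),
        sigma_phi=float(row["sigma_phi"]),
    )


def run_table1_reproduction(
    strains: pd.DataFrame,
    n_traj: int = 100_000,
    n_steps: int = 30,
    seed: int = 0,
    noise: str = "cos",
) -> pd.DataFrame:
    """Per-strain side-by-side report of predicted correlation factors.

    For every strain row the closed-form per-step correlation factor is
    evaluated from the five parameters, a seeded ensemble is simulated
    and fitted for the Monte Carlo correlation factor, and both are
    converted to mean turn angles.  If a ``gamma_obs`` column is present
    the absolute deviations from it are reported.  Errors in one strain
    are recorded in an ``error`` column without aborting the others.
    """
    records = []
    for offset, (_, row) in enumerate(strains.iterrows()):
        rec = {"strain": row["strain"]}
        try:
            params = params_from_row(row)
            lam = step_size(params.lambda_p, params.phi)
            g_step = gamma_step(params, noise=noise)
            fit = fit_crw(
                ensemble_msd(params, n_traj, n_steps, seed=seed + offset), lam
            )
            rec.update(
                lam=lam,
                gamma_step=g_step,
                gamma_mc=fit.gamma,
                theta_step=turn_angle(g_step),
                theta_mc=turn_angle(np.clip(fit.gamma, -1.0, 1.0)),
                error="",
            )
            if "gamma_obs" in strains.columns and pd.notna(row.get("gamma_obs")):
                g_obs = float(row["gamma_obs"])
                rec.update(
                    gamma_obs=g_obs,
                    dev_step=abs(g_step - g_obs),
                    dev_mc=abs(fit.gamma - g_obs),
                )
            logger.info(
                "strain %s: gamma_step=%.3f gamma_mc=%.3f (n_traj=%d, seed=%d)",
                row["strain"], g_step, fit.gamma, n_traj, seed + offset,
            )
        except Exception as exc:  # keep processing remaining strains
            rec["error"] = str(exc)
            logger.warning("strain %s failed: %s", row["strain"], exc)
        records.append(rec)
    return pd.DataFrame(records)
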