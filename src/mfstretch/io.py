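"""Format glue: CSV/JSON/YAML readers and writers for the pipeline.

CSV dialect is comma-separated with '.' decimals and a mandatory header row.
Traces use columns (t_s, xs_m, x_m, F_N); group tables use
(group, mouse_id, E_Pa, ...); droplet observations use (a_m, b_m, dx_m).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aggregate_sim import GroundTruth, SimulatedTrace
from .calibration import CantileverCalibration, DropletObservation
from .tracking import GeometryMeasurement, TrackResult

TRACE_COLUMNS = ["t_s", "xs_m", "x_m", "F_N"]


def write_trace_csv(trace, path: str | Path) -> None:
    """Write a deflection trace (simulated or tracked) as CSV."""
    t = np.asarray(trace.t, dtype=float)
    x = np.asarray(trace.x, dtype=float)
    x_s = getattr(trace, "x_s", None)
    f = getattr(trace, "F", None)
    df = pd.DataFrame(
        {
            "t_s": t,
            "xs_m": np.asarray(x_s, dtype=float) if x_s is not None else np.full_like(t, np.nan),
            "x_m": x,
            "F_N": np.asarray(f, dtype=float) if f is not None else np.full_like(t, np.nan),
        }
    )
    df.to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> SimulatedTrace:
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV {path} missing columns {missing}")
    xs = df["xs_m"].to_numpy()
    return SimulatedTrace(
        t=df["t_s"].to_numpy(),
        x_s=xs,
        x=df["x_m"].to_numpy(),
        F=df["F_N"].to_numpy(),
        ruptured_at=None,
    )


def write_track_csv(result: TrackResult, path: str | Path) -> None:
    pd.DataFrame(
        {
            "t_s": result.t,
            "tip_x_px": result.tip_x,
            "tip_y_px": result.tip_y,
            "x_m": result.x,
            "quality": result.quality,
        }
    ).to_csv(path, index=False)


def geometry_to_json(geom: GeometryMeasurement, path: str | Path | None = None) -> str:
    payload = {
        "R0_mean_m": geom.R0_mean, "R0_sd_m": geom.R0_sd,
        "L0_mean_m": geom.L0_mean, "L0_sd_m": geom.L0_sd,
        "n_repeats": geom.n_repeats, "V_m3": geom.V,
        "V_tot_m3": geom.V_tot,
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def geometry_from_json(path: str | Path) -> GeometryMeasurement:
    d = json.loads(Path(path).read_text())
    return GeometryMeasurement(
        R0_mean=d["R0_mean_m"], R0_sd=d["R0_sd_m"],
        L0_mean=d["L0_mean_m"], L0_sd=d["L0_sd_m"],
        n_repeats=d.get("n_repeats", 5), V_tot=d.get("V_tot_m3"),
    )


def calibration_to_json(cal: CantileverCalibration, path: str | Path | None = None) -> str:
    payload = {
        "k_p_mean_N_per_m": cal.k_p_mean, "k_p_sd_N_per_m": cal.k_p_sd,
        "n_obs": cal.n_obs, "rho_kg_per_m3": cal.rho, "g_m_per_s2": cal.g,
        "low_replication": cal.low_replication,
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def calibration_from_json(path: str | Path) -> CantileverCalibration:
    d = json.loads(Path(path).read_text())
    return CantileverCalibration(
        k_p_mean=d["k_p_mean_N_per_m"], k_p_sd=d["k_p_sd_N_per_m"],
        n_obs=d.get("n_obs", 1), rho=d.get("rho_kg_per_m3", 1000.0),
        g=d.get("g_m_per_s2", 9.81),
        low_replication=d.get("low_replication", False),
    )


def read_droplet_csv(path: str | Path) -> list[DropletObservation]:
    df = pd.read_csv(path)
    missing = [c for c in ("a_m", "b_m", "dx_m") if c not in df.columns]
    if missing:
        raise ValueError(f"droplet CSV {path} missing columns {missing}")
    return [
        DropletObservation(a=row.a_m, b=row.b_m, delta_x=row.dx_m)
        for row in df.itertuples()
    ]


def write_droplet_csv(obs: list[DropletObservation], path: str | Path) -> None:
    pd.DataFrame(
        {"a_m": [o.a for o in obs], "b_m": [o.b for o in obs],
         "dx_m": [o.delta_x for o in obs]}
    ).to_csv(path, index=False)


def ground_truth_to_json(truth: GroundTruth, path: str | Path | None = None) -> str:
    payload = {
        "E_true_Pa": truth.E_true,
        "sigma_uts_true_Pa": truth.sigma_uts_true,
        "R0_m": truth.R0, "L0_m": truth.L0,
        "k_eff0_N_per_m": truth.k_eff0,
        "cell": {
            "r_c_m": truth.cell.r_c, "k_c_N_per_m": truth.cell.k_c,
            "yield_strain": truth.cell.yield_strain,
            "rupture_strain": truth.cell.rupture_strain,
        },
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON run configuration into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        return yaml.safe_load(text)
    return json.loads(text)
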