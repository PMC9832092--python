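"""Configuration, unit handling, and CSV/JSON/VTK output.

All configs are JSON with unit-suffixed keys (``Rp_mmHg_s_mL``, ``T_s``,
``EOA_cm2``); dimensionless quantities are whitelisted by name.  Unknown
keys and numeric keys without a recognized unit suffix are hard errors, so
silent typos cannot change a simulation.  Conversion constants:
1 mmHg = 1333.22 dyn/cm^2, 1 Fr = 1/3 mm, 1 MPa = 1000 kPa.

Geometry snapshots are written as VTK legacy ASCII (polydata for Lagrangian
structures, structured points for Eulerian fields); waveforms and metrics
as CSV/JSON.  Outputs carry a manifest (config hash, seed, package version)
and identical runs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .circulation import CirculationParams, TwoHillElastance, ValveSurrogate
from .hgo import HGOParams

__all__ = [
    "DYN_CM2_PER_MMHG",
    "MM_PER_FR",
    "KPA_PER_MPA",
    "mmHg_to_dyn_cm2",
    "dyn_cm2_to_mmHg",
    "fr_to_mm",
    "mm_to_fr",
    "load_config",
    "config_hash",
    "default_config_path",
    "circulation_params_from_config",
    "circulation_params_to_config",
    "valve_from_config",
    "hgo_params_from_json",
    "write_waveforms",
    "read_waveforms",
    "write_metrics",
    "write_manifest",
    "write_vtk_polydata",
    "write_vtk_structured_points",
]

DYN_CM2_PER_MMHG = 1333.22
MM_PER_FR = 1.0 / 3.0
KPA_PER_MPA = 1000.0


def mmHg_to_dyn_cm2(p):
    return np.asarray(p, dtype=float) * DYN_CM2_PER_MMHG


def dyn_cm2_to_mmHg(p):
    return np.asarray(p, dtype=float) / DYN_CM2_PER_MMHG


def fr_to_mm(d):
    return np.asarray(d, dtype=float) * MM_PER_FR


def mm_to_fr(d):
    return np.asarray(d, dtype=float) / MM_PER_FR


# ---------------------------------------------------------------------------
# config loading / validation

_UNIT_SUFFIXES = (
    "_kPa", "_MPa", "_mmHg", "_mmHg_s_mL", "_mmHg_mL", "_mL_mmHg", "_mL_s",
    "_L_min", "_mL", "_s", "_cm", "_cm2", "_cm_s", "_mm", "_Fr", "_deg",
    "_dyne_cm", "_dyne_s_cm", "_erg", "_frac_T", "_g_cm3", "_P", "_cP",
    "_per_cm",
)

_DIMENSIONLESS = {
    "m1", "m2", "k2", "C01", "n_cycles", "n_circumferential", "n_rows",
    "seed", "N", "Nx", "Ny", "n_points", "factor", "aspect", "la_shift_sign",
    "kind", "name", "module", "noise_rel", "wall_frac",
}


def _check_keys(d: dict, path: str = "") -> None:
    for k, v in d.items():
        here = f"{path}.{k}" if path else k
        if isinstance(v, dict):
            _check_keys(v, here)
        elif isinstance(v, (int, float)) and not isinstance(v, bool):
            if k in _DIMENSIONLESS or any(k.endswith(s) for s in _UNIT_SUFFIXES):
                continue
            raise ValueError(
                f"config key '{here}' is numeric but carries no recognized "
                f"unit suffix; suffix it (e.g. '{k}_s', '{k}_mmHg') or use a "
                "whitelisted dimensionless name"
            )


def load_config(path: str | Path) -> dict:
    """Load a JSON config, enforcing unit-suffixed numeric keys."""
    path = Path(path)
    with open(path) as fh:
        cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must contain a JSON object")
    _check_keys(cfg)
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a canonicalized config dict."""
    blob = json.dumps(cfg, sort_keys=True, separators=(",", ":")).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def default_config_path(name: str) -> Path:
    """Path of a shipped example config (e.g. 'circulation_default')."""
    p = Path(__file__).parent / "configs" / f"{name}.json"
    if not p.exists():
        raise FileNotFoundError(f"no shipped config named {name!r}")
    return p


def _elastance_from_config(d: dict, T: float) -> TwoHillElastance:
    return TwoHillElastance.from_fractions(
        d["tau1_frac_T"], d["tau2_frac_T"], d["m1"], d["m2"],
        d["Emin_mmHg_mL"], d["Emax_mmHg_mL"], T,
    )


def circulation_params_from_config(cfg: dict) -> CirculationParams:
    T = float(cfg["T_s"])
    return CirculationParams(
        Qvein_mL_s=float(cfg["Qvein_L_min"]) * 1000.0 / 60.0,
        Rmv=float(cfg["Rmv_mmHg_s_mL"]),
        Rlvot=float(cfg["Rlvot_mmHg_s_mL"]),
        Rc=float(cfg["Rc_mmHg_s_mL"]),
        Rp=float(cfg["Rp_mmHg_s_mL"]),
        Cwk=float(cfg["C_mL_mmHg"]),
        T=T,
        elastance_lv=_elastance_from_config(cfg["elastance_LV"], T),
        elastance_la=_elastance_from_config(cfg["elastance_LA"], T),
        la_shift_frac=float(cfg.get("la_shift_frac_T", 0.85)),
        la_shift_sign=cfg.get("la_shift_sign", "delay"),
    )


def circulation_params_to_config(p: CirculationParams) -> dict:
    def edict(e: TwoHillElastance) -> dict:
        return {
            "tau1_frac_T": e.tau1_s / p.T,
            "tau2_frac_T": e.tau2_s / p.T,
            "m1": e.m1,
            "m2": e.m2,
            "Emin_mmHg_mL": e.Emin,
            "Emax_mmHg_mL": e.Emax,
        }

    return {
        "Qvein_L_min": p.Qvein_mL_s * 60.0 / 1000.0,
        "Rmv_mmHg_s_mL": p.Rmv,
        "Rlvot_mmHg_s_mL": p.Rlvot,
        "Rc_mmHg_s_mL": p.Rc,
        "Rp_mmHg_s_mL": p.Rp,
        "C_mL_mmHg": p.Cwk,
        "T_s": p.T,
        "elastance_LV": edict(p.elastance_lv),
        "elastance_LA": edict(p.elastance_la),
        "la_shift_frac_T": p.la_shift_frac,
        "la_shift_sign": p.la_shift_sign,
    }


def valve_from_config(cfg: dict) -> ValveSurrogate:
    kind = cfg.get("kind", "orifice")
    return ValveSurrogate(
        kind=kind,
        EOA_cm2=float(cfg.get("EOA_cm2", 1.5)),
        R=float(cfg.get("R_mmHg_s_mL", 0.0)),
    )


def hgo_params_from_json(path: str | Path) -> HGOParams:
    return HGOParams.from_dict(load_config(path))


# ---------------------------------------------------------------------------
# output writers

def write_waveforms(df: pd.DataFrame, path: str | Path) -> None:
    """Full-precision CSV; re-reading reproduces the arrays exactly."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")


def read_waveforms(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_metrics(metrics: dict, path: str | Path, cfg: dict | None = None,
                  seed: int | None = None) -> None:
    out = dict(metrics)
    if cfg is not None:
        out["config_hash"] = config_hash(cfg)
    if seed is not None:
        out["seed"] = seed
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def write_manifest(path: str | Path, cfg: dict, seed: int | None = None,
                   extra: dict | None = None) -> None:
    from . import __version__

    man = {
        "tavrom_version": __version__,
        "config_hash": config_hash(cfg),
        "config": cfg,
        "seed": seed,
    }
    if extra:
        man.update(extra)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(man, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def write_vtk_polydata(path: str | Path, points: np.ndarray,
                       lines: np.ndarray | None = None,
                       point_scalars: dict[str, np.ndarray] | None = None) -> None:
    """Write points (+ optional line cells and scalars) as VTK legacy ASCII."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] not in (2, 3):
        raise ValueError("points must be (N, 2) or (N, 3)")
    if points.shape[1] == 2:
        points = np.column_stack([points, np.zeros(len(points))])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ntavrom geometry\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} double\n")
        for p in points:
            fh.write(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
        if lines is not None and len(lines):
            lines = np.asarray(lines, dtype=int)
            fh.write(f"LINES {len(lines)} {3 * len(lines)}\n")
            for a, b in lines:
                fh.write(f"2 {a} {b}\n")
        if point_scalars:
            fh.write(f"POINT_DATA {len(points)}\n")
            for name, arr in point_scalars.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for val in np.asarray(arr, dtype=float):
                    fh.write(f"{val:.12g}\n")


def write_vtk_structured_points(path: str | Path, fields: dict[str, np.ndarray],
                                spacing: float, origin=(0.0, 0.0, 0.0)) -> None:
    """Write 2D cell-centred scalar fields as VTK legacy STRUCTURED_POINTS."""
    shapes = {f.shape for f in fields.values()}
    if len(shapes) != 1:
        raise ValueError("all fields must share one shape")
    nx, ny = shapes.pop()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ntavrom field\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} 1\n")
        fh.write(f"ORIGIN {origin[0]:g} {origin[1]:g} {origin[2]:g}\n")
        fh.write(f"SPACING {spacing:g} {spacing:g} 1\n")
        fh.write(f"POINT_DATA {nx * ny}\n")
        for name, arr in fields.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            for val in np.asarray(arr, dtype=float).T.ravel():
                fh.write(f"{val:.12g}\n")
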