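"""Run configuration, validation, and on-disk artifacts.

A run is fully described by a small YAML config; loading fills defaults
(reference parameter set, production solver settings) and validates every
field, reporting all violations at once.  ``run_simulate`` executes the
pipeline and writes plain-text artifacts (fields CSV, trajectory CSV,
summary JSON) plus an optional compressed field archive and synthetic TIFF
stack.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ContractError, SolverError
from .front_analysis import FrontTrajectory, build_trajectory
from .kinetics import ModelParameters
from .scenarios import Scenario, make_disc_scenario, make_sphere_scenario
from .solver import SimulationResult, SolverOptions, integrate

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "run_simulate",
    "write_summary",
    "trajectory_to_csv",
    "trajectory_from_csv",
]

logger = logging.getLogger("gelfront")

#: Aliases accepted in configs/CLI for the compact parameter spellings.
PARAM_ALIASES = {
    "D0poly": "D0_poly",
    "D0ba": "D0_ba",
    "Kpoly": "K_poly",
    "Kba": "K_ba",
    "Cpoly": "C_poly",
    "Cba": "C_ba",
    "Ckba": "C_kba",
    "Ck": "C_k",
}

#: Config parameter keys carry physical diffusivity units (m^2/s); internal
#: model units are mm^2/s.
_M2S_TO_MM2S = 1e6

_TOP_KEYS = {
    "geometry",
    "bath_mM",
    "diameter_um",
    "volume_uL",
    "height_um",
    "n_nodes",
    "horizon_s",
    "output_cadence_s",
    "parameters",
    "solver",
    "imaging",
    "seed",
    "out_dir",
    "log_level",
    "label",
}
_SOLVER_KEYS = {"rtol", "atol", "method"}
_IMAGING_KEYS = {"render", "pixel_size_um", "noise_sigma", "frame_stride"}
_PARAM_KEYS = set(PARAM_ALIASES) | set(PARAM_ALIASES.values())


@dataclass
class RunConfig:
    """Validated, fully-defaulted description of one simulation run."""

    geometry: str = "disc"
    bath_mM: float = 20.0
    diameter_um: Optional[float] = None  # spheres only
    volume_uL: float = 4.0  # discs only
    height_um: float = 200.0  # discs only
    n_nodes: int = 600
    horizon_s: Optional[float] = None
    output_cadence_s: Optional[float] = None
    params: ModelParameters = field(default_factory=ModelParameters.default)
    solver: SolverOptions = field(default_factory=SolverOptions)
    render_images: bool = False
    pixel_size_um: float = 10.0
    noise_sigma: float = 0.05
    frame_stride: int = 4
    seed: int = 0
    out_dir: str = "gelfront_out"
    log_level: str = "INFO"
    label: str = ""

    def scenario(self) -> Scenario:
        common = dict(
            n_nodes=self.n_nodes,
            horizon_s=self.horizon_s,
            output_cadence_s=self.output_cadence_s,
            label=self.label or None,
        )
        if self.geometry == "disc":
            return make_disc_scenario(
                self.bath_mM,
                self.params,
                volume_uL=self.volume_uL,
                height_um=self.height_um,
                **common,
            )
        return make_sphere_scenario(
            self.diameter_um, self.bath_mM, self.params, **common
        )

    def to_dict(self) -> Dict[str, Any]:
        p = self.params
        return {
            "geometry": self.geometry,
            "bath_mM": self.bath_mM,
            "diameter_um": self.diameter_um,
            "volume_uL": self.volume_uL,
            "height_um": self.height_um,
            "n_nodes": self.n_nodes,
            "horizon_s": self.horizon_s,
            "output_cadence_s": self.output_cadence_s,
            "parameters": {
                "D0_poly_m2_s": p.D0_poly / _M2S_TO_MM2S,
                "D0_ba_m2_s": p.D0_ba / _M2S_TO_MM2S,
                "K_poly": p.K_poly,
                "K_ba": p.K_ba,
                "C_poly": p.C_poly,
                "C_ba": p.C_ba,
                "C_kba": p.C_kba,
                "C_k": p.C_k,
            },
            "solver": {
                "rtol": self.solver.rtol,
                "atol": self.solver.atol,
                "method": self.solver.method,
            },
            "imaging": {
                "render": self.render_images,
                "pixel_size_um": self.pixel_size_um,
                "noise_sigma": self.noise_sigma,
                "frame_stride": self.frame_stride,
            },
            "seed": self.seed,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
            "label": self.label,
        }


def _coerce_params(
    raw: Dict[str, Any], errors: List[str]
) -> ModelParameters:
    defaults = ModelParameters.default()
    kwargs: Dict[str, float] = {}
    for key, value in raw.items():
        name = PARAM_ALIASES.get(key, key)
        if name.endswith("_m2_s"):
            name = name[: -len("_m2_s")]
            value = float(value) * _M2S_TO_MM2S
        if name not in PARAM_ALIASES.values():
            errors.append(f"parameters: unknown key {key!r}")
            continue
        kwargs[name] = float(value)
    try:
        return defaults.with_updates(**kwargs)
    except ContractError as exc:
        errors.append(str(exc))
        return defaults


def _from_dict(data: Dict[str, Any]) -> RunConfig:
    errors: List[str] = []
    unknown = set(data) - _TOP_KEYS
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")

    raw_params = data.get("parameters") or {}
    # parameter keys may carry the _m2_s suffix for diffusivities
    cleaned = {}
    for k, v in raw_params.items():
        base = k[: -len("_m2_s")] if k.endswith("_m2_s") else k
        if base not in _PARAM_KEYS:
            errors.append(f"parameters: unknown key {k!r}")
        else:
            cleaned[k] = v
    params = _coerce_params(cleaned, errors)

    raw_solver = data.get("solver") or {}
    unknown = set(raw_solver) - _SOLVER_KEYS
    if unknown:
        errors.append(f"solver: unknown keys {sorted(unknown)}")
    try:
        solver = SolverOptions(
            rtol=float(raw_solver.get("rtol", 1e-6)),
            atol=float(raw_solver.get("atol", 1e-10)),
            method=str(raw_solver.get("method", "BDF")),
        )
    except ContractError as exc:
        errors.append(str(exc))
        solver = SolverOptions()

    raw_imaging = data.get("imaging") or {}
    unknown = set(raw_imaging) - _IMAGING_KEYS
    if unknown:
        errors.append(f"imaging: unknown keys {sorted(unknown)}")

    geometry = str(data.get("geometry", "disc"))
    if geometry not in ("disc", "sphere"):
        errors.append(f"geometry must be 'disc' or 'sphere', got {geometry!r}")
    bath = float(data.get("bath_mM", 20.0))
    if bath <= 0.0:
        errors.append(f"bath_mM must be > 0, got {bath}")
    diameter = data.get("diameter_um")
    if geometry == "sphere" and diameter is None:
        errors.append("sphere geometry requires diameter_um")
    if errors:
        raise ConfigError(
            "invalid configuration:\n  - " + "\n  - ".join(errors)
        )

    return RunConfig(
        geometry=geometry,
        bath_mM=bath,
        diameter_um=None if diameter is None else float(diameter),
        volume_uL=float(data.get("volume_uL", 4.0)),
        height_um=float(data.get("height_um", 200.0)),
        n_nodes=int(data.get("n_nodes", 600)),
        horizon_s=None if data.get("horizon_s") is None else float(data["horizon_s"]),
        output_cadence_s=(
            None if data.get("output_cadence_s") is None
            else float(data["output_cadence_s"])
        ),
        params=params,
        solver=solver,
        render_images=bool(raw_imaging.get("render", False)),
        pixel_size_um=float(raw_imaging.get("pixel_size_um", 10.0)),
        noise_sigma=float(raw_imaging.get("noise_sigma", 0.05)),
        frame_stride=int(raw_imaging.get("frame_stride", 4)),
        seed=int(data.get("seed", 0)),
        out_dir=str(data.get("out_dir", "gelfront_out")),
        log_level=str(data.get("log_level", "INFO")),
        label=str(data.get("label", "")),
    )


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML run config, filling all defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data)}")
    return _from_dict(data)


def save_config(config: RunConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def trajectory_to_csv(traj: FrontTrajectory, path: Union[str, Path]) -> None:
    pd.DataFrame(
        {
            "time_s": traj.times,
            "front_radius_mm": traj.front_radius,
            "front_diameter_mm": traj.front_diameter,
        }
    ).to_csv(path, index=False)


def trajectory_from_csv(path: Union[str, Path]) -> FrontTrajectory:
    df = pd.read_csv(path)
    radii = df["front_radius_mm"].to_numpy(dtype=float)
    finite = radii[np.isfinite(radii)]
    R0 = float(finite[0]) if finite.size else float("nan")
    return FrontTrajectory(
        times=df["time_s"].to_numpy(dtype=float),
        front_radius=radii,
        R0=R0,
    )


def write_summary(
    traj: FrontTrajectory, path: Optional[Union[str, Path]] = None
) -> Dict[str, Any]:
    """Build (and optionally write) the run summary JSON document.

    Velocities follow the shrinking-core sign convention (negative).
    """
    doc: Dict[str, Any] = {
        "R0_mm": traj.R0,
        "gelation_time_s": traj.gelation_time,
        "breakpoint_s": traj.breakpoint_s,
        "v_early_mm_per_s": traj.v_early,
        "v_late_mm_per_s": traj.v_late,
        "units": {
            "radius": "mm",
            "time": "s",
            "velocity": "mm/s",
        },
    }
    if traj.gelation_time is None:
        doc["gelation_time_reason"] = "front did not reach the core within the horizon"
    if traj.fit is not None and traj.fit.degenerate:
        doc["fit_warning"] = "trajectory is effectively linear; breakpoint unidentifiable"
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=2))
    return doc


def _fields_dataframe(result: SimulationResult) -> pd.DataFrame:
    n_t, n_r = result.rho_poly.shape
    t = np.repeat(result.times, n_r)
    r = np.tile(result.grid.r, n_t)
    return pd.DataFrame(
        {
            "time_s": t,
            "radius_mm": r,
            "rho_poly": result.rho_poly.ravel(),
            "rho_ba": result.rho_ba.ravel(),
            "rho_cross": result.rho_cross.ravel(),
            "kappa": result.kappa.ravel(),
        }
    )


def run_simulate(config: RunConfig) -> Dict[str, Path]:
    """Execute a configured run and write all artifacts.

    Returns a mapping of artifact names to paths.  On solver failure the
    partially-written directory receives a FAILED marker file and the error
    propagates.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.yaml")
    scenario = config.scenario()
    logger.info(
        "simulating %s: R0=%.3f mm, bath=%g mM, horizon=%.0f s, %d nodes",
        scenario.label, scenario.R0, config.bath_mM, scenario.horizon,
        scenario.grid.n,
    )
    try:
        result = integrate(scenario, config.params, config.solver)
    except SolverError:
        (out / "FAILED").write_text("solver failure; outputs are partial\n")
        raise
    logger.info("solver done: %d rhs evaluations", result.nfev)

    artifacts: Dict[str, Path] = {}
    fields_csv = out / "fields.csv"
    # cap the CSV at ~60 snapshots; the archive keeps everything
    stride = max(1, len(result) // 60)
    sub = _fields_dataframe(
        SimulationResult(
            grid=result.grid,
            times=result.times[::stride],
            rho_poly=result.rho_poly[::stride],
            rho_ba=result.rho_ba[::stride],
            rho_cross=result.rho_cross[::stride],
            kappa=result.kappa[::stride],
            params=result.params,
            bath_ba=result.bath_ba,
        )
    )
    sub.to_csv(fields_csv, index=False)
    artifacts["fields_csv"] = fields_csv

    archive = out / "fields.npz"
    np.savez_compressed(
        archive,
        times=result.times,
        radii=result.grid.r,
        rho_poly=result.rho_poly,
        rho_ba=result.rho_ba,
        rho_cross=result.rho_cross,
        kappa=result.kappa,
    )
    artifacts["fields_archive"] = archive

    traj = build_trajectory(result, config.params)
    traj_csv = out / "trajectory.csv"
    trajectory_to_csv(traj, traj_csv)
    artifacts["trajectory_csv"] = traj_csv

    summary_path = out / "summary.json"
    write_summary(traj, summary_path)
    artifacts["summary_json"] = summary_path
    if traj.gelation_time is not None:
        logger.info("gelation complete at t=%.0f s", traj.gelation_time)

    if config.render_images:
        from .imaging import ImagingNoiseModel, render_series

        series = render_series(
            result,
            config.params,
            pixel_size_um=config.pixel_size_um,
            noise=ImagingNoiseModel(
                sigma=config.noise_sigma, seed=config.seed
            ),
            frame_stride=config.frame_stride,
        )
        tiff = out / "synthetic_stack.tiff"
        series.save_tiff(tiff)
        artifacts["synthetic_stack"] = tiff
    return artifacts
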