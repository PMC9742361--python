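"""JSON configuration loading and saving.

Configurations are strict: unknown keys are errors (a silently ignored
typo in a rate constant is the main user hazard), and quantities carry
their unit in the key name.  The diffusion coefficient may be given with
an explicit unit tag (``{"value": 2e-5, "unit": "cm^2/s"}``) and is
converted once, at load time, to the canonical μm²/s.

Top-level keys: ``tissue``, ``grid``, ``geometry``, ``boundary``,
``protocols``.  Omitted tissue parameters fall back to the built-in
defaults of :class:`~flashox.parameters.TissueParameters`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

from .geometry import (Geometry1D, Geometry2D, Geometry3D, GridSpec,
                       VesselSegment2D)
from .parameters import (BoundarySupply, InvalidParameterError,
                         IrradiationProtocol, TissueParameters)

_CM2_PER_UM2 = 1e-8


class ConfigError(ValueError):
    """The configuration file is invalid; the message names the field."""


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _diffusion_um2_s(raw: Any) -> float:
    """Accept a plain μm²/s number or a unit-tagged value."""
    if isinstance(raw, dict):
        _check_keys(raw, {"value", "unit"}, "tissue.k3_diffusion")
        unit = raw.get("unit", "um^2/s")
        value = raw["value"]
        if unit in ("um^2/s", "um2/s"):
            return float(value)
        if unit in ("cm^2/s", "cm2/s"):
            return float(value) / _CM2_PER_UM2
        raise ConfigError(f"tissue.k3_diffusion: unsupported unit {unit!r}")
    return float(raw)


def _tissue(block: dict) -> TissueParameters:
    _check_keys(block, {"k1_depletion_uM_per_Gy", "l_depletion_uM",
                        "k2_metabolism_uM_per_s", "lambda_metabolism_uM",
                        "k3_diffusion"}, "tissue")
    defaults = TissueParameters()
    try:
        return TissueParameters(
            k1_depletion=float(block.get("k1_depletion_uM_per_Gy",
                                         defaults.k1_depletion)),
            l_depletion=float(block.get("l_depletion_uM",
                                        defaults.l_depletion)),
            k2_metabolism=float(block.get("k2_metabolism_uM_per_s",
                                          defaults.k2_metabolism)),
            lambda_metabolism=float(block.get("lambda_metabolism_uM",
                                              defaults.lambda_metabolism)),
            k3_diffusion=_diffusion_um2_s(
                block.get("k3_diffusion", defaults.k3_diffusion)),
        )
    except InvalidParameterError as exc:
        raise ConfigError(f"tissue: {exc}") from exc


def _grid(block: dict) -> GridSpec:
    _check_keys(block, {"dx_um", "steps_per_stage", "recovery_duration_s",
                        "equilibration_tolerance",
                        "equilibration_residual_tol",
                        "equilibration_max_time_s",
                        "irradiation_snapshot_stride",
                        "other_snapshot_stride"}, "grid")
    d = GridSpec()
    return GridSpec(
        dx=float(block.get("dx_um", d.dx)),
        steps_per_stage=int(block.get("steps_per_stage", d.steps_per_stage)),
        recovery_duration=float(block.get("recovery_duration_s",
                                          d.recovery_duration)),
        equilibration_tolerance=float(block.get(
            "equilibration_tolerance", d.equilibration_tolerance)),
        equilibration_residual_tol=float(block.get(
            "equilibration_residual_tol", d.equilibration_residual_tol)),
        equilibration_max_time=float(block.get(
            "equilibration_max_time_s", d.equilibration_max_time)),
        irradiation_snapshot_stride=int(block.get(
            "irradiation_snapshot_stride", d.irradiation_snapshot_stride)),
        other_snapshot_stride=int(block.get(
            "other_snapshot_stride", d.other_snapshot_stride)),
    )


def _supply(block: dict, where: str) -> BoundarySupply:
    _check_keys(block, {"base_level_uM", "transient", "alpha", "tau_s",
                        "onset_s"}, where)
    if "base_level_uM" not in block:
        raise ConfigError(f"{where}: base_level_uM is required")
    try:
        return BoundarySupply(
            base_level=float(block["base_level_uM"]),
            transient=bool(block.get("transient", False)),
            alpha=float(block.get("alpha", 0.0)),
            tau=float(block.get("tau_s", 10.0)),
            onset=float(block.get("onset_s", 0.0)))
    except InvalidParameterError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def _geometry(block: dict, default_supply: BoundarySupply):
    if "kind" not in block:
        raise ConfigError("geometry: kind is required (1d, 2d_rect, 3d_cuboid)")
    kind = block["kind"]
    if kind == "1d":
        _check_keys(block, {"kind", "spacing_um", "left_supply",
                            "right_supply"}, "geometry")
        if "spacing_um" not in block:
            raise ConfigError("geometry: spacing_um is required for kind 1d")
        left = (_supply(block["left_supply"], "geometry.left_supply")
                if "left_supply" in block else default_supply)
        right = (_supply(block["right_supply"], "geometry.right_supply")
                 if "right_supply" in block else default_supply)
        return Geometry1D(float(block["spacing_um"]), left, right)
    if kind == "3d_cuboid":
        _check_keys(block, {"kind", "cross_section_side_um",
                            "center_to_edge_um", "height_um",
                            "vessel_radius_um"}, "geometry")
        if "center_to_edge_um" in block:
            if "cross_section_side_um" in block:
                raise ConfigError(
                    "geometry: give cross_section_side_um or "
                    "center_to_edge_um, not both")
            geom = Geometry3D.from_center_to_edge_distance(
                float(block["center_to_edge_um"]),
                height=(float(block["height_um"])
                        if "height_um" in block else None),
                vessel_radius=float(block.get("vessel_radius_um", 5.0)),
                supply=default_supply)
            return geom
        if "cross_section_side_um" not in block:
            raise ConfigError("geometry: cross_section_side_um or "
                              "center_to_edge_um is required for 3d_cuboid")
        side = float(block["cross_section_side_um"])
        return Geometry3D(side, float(block.get("height_um", side)),
                          float(block.get("vessel_radius_um", 5.0)),
                          default_supply)
    if kind == "2d_rect":
        _check_keys(block, {"kind", "width_um", "height_um",
                            "border_supplies", "vessels"}, "geometry")
        for key in ("width_um", "height_um", "border_supplies"):
            if key not in block:
                raise ConfigError(f"geometry: {key} is required for 2d_rect")
        borders = {side: _supply(b, f"geometry.border_supplies.{side}")
                   for side, b in block["border_supplies"].items()}
        vessels = []
        for i, v in enumerate(block.get("vessels", [])):
            _check_keys(v, {"start_um", "end_um", "radius_um", "supply"},
                        f"geometry.vessels[{i}]")
            vessels.append(VesselSegment2D(
                tuple(v["start_um"]), tuple(v["end_um"]),
                float(v["radius_um"]),
                _supply(v["supply"], f"geometry.vessels[{i}].supply")))
        return Geometry2D(float(block["width_um"]), float(block["height_um"]),
                          borders, tuple(vessels))
    raise ConfigError(f"geometry: unknown kind {kind!r}")


def _protocols(block: list) -> list[IrradiationProtocol]:
    out = []
    for i, p in enumerate(block):
        _check_keys(p, {"label", "dose_Gy", "dose_rate_Gy_per_s",
                        "let_kev_per_um"}, f"protocols[{i}]")
        for key in ("dose_Gy", "dose_rate_Gy_per_s"):
            if key not in p:
                raise ConfigError(f"protocols[{i}]: {key} is required")
        try:
            out.append(IrradiationProtocol(
                dose=float(p["dose_Gy"]),
                dose_rate=float(p["dose_rate_Gy_per_s"]),
                let_d=float(p.get("let_kev_per_um", 1.2)),
                label=str(p.get("label", f"protocol{i}"))))
        except InvalidParameterError as exc:
            raise ConfigError(f"protocols[{i}]: {exc}") from exc
    return out


def load_config(path: str | Path):
    """Parse and validate a configuration file.

    Returns ``(tissue, grid, geometry, protocols)``.  Raises
    :class:`ConfigError` naming the offending field on any problem.
    """
    raw = json.loads(Path(path).read_text())
    _check_keys(raw, {"tissue", "grid", "geometry", "boundary", "protocols"},
                "the top level")
    if "geometry" not in raw:
        raise ConfigError("geometry block is required")
    tissue = _tissue(raw.get("tissue", {}))
    if tissue.k3_diffusion <= 0:
        raise ConfigError("tissue.k3_diffusion must be > 0")
    grid = _grid(raw.get("grid", {}))
    default_supply = (_supply(raw["boundary"], "boundary")
                      if "boundary" in raw else BoundarySupply(50.4))
    geometry = _geometry(raw["geometry"], default_supply)
    protocols = _protocols(raw.get("protocols", []))
    return tissue, grid, geometry, protocols


def _supply_dict(s: BoundarySupply) -> dict:
    out: dict = {"base_level_uM": s.base_level}
    if s.transient:
        out.update(transient=True, alpha=s.alpha, tau_s=s.tau,
                   onset_s=s.onset)
    return out


def save_config(path: str | Path, tissue: TissueParameters, grid: GridSpec,
                geometry, protocols: list[IrradiationProtocol]) -> None:
    """Write a configuration that :func:`load_config` round-trips exactly."""
    geom: dict
    if isinstance(geometry, Geometry1D):
        geom = {"kind": "1d", "spacing_um": geometry.spacing,
                "left_supply": _supply_dict(geometry.left_supply),
                "right_supply": _supply_dict(geometry.right_supply)}
        boundary = _supply_dict(geometry.left_supply)
    elif isinstance(geometry, Geometry3D):
        geom = {"kind": "3d_cuboid",
                "cross_section_side_um": geometry.cross_section_side,
                "height_um": geometry.height,
                "vessel_radius_um": geometry.vessel_radius}
        boundary = _supply_dict(geometry.supply)
    elif isinstance(geometry, Geometry2D):
        geom = {"kind": "2d_rect", "width_um": geometry.width,
                "height_um": geometry.height,
                "border_supplies": {side: _supply_dict(s) for side, s
                                    in geometry.border_supplies.items()},
                "vessels": [{"start_um": list(v.start),
                             "end_um": list(v.end),
                             "radius_um": v.radius,
                             "supply": _supply_dict(v.supply)}
                            for v in geometry.vessels]}
        boundary = next(iter(_supply_dict(s) for s in
                             geometry.border_supplies.values()),
                        {"base_level_uM": 50.4})
    else:
        raise ConfigError(f"cannot serialize geometry {type(geometry)}")
    doc = {
        "tissue": {
            "k1_depletion_uM_per_Gy": tissue.k1_depletion,
            "l_depletion_uM": tissue.l_depletion,
            "k2_metabolism_uM_per_s": tissue.k2_metabolism,
            "lambda_metabolism_uM": tissue.lambda_metabolism,
            "k3_diffusion": tissue.k3_diffusion,
        },
        "grid": {
            "dx_um": grid.dx,
            "steps_per_stage": grid.steps_per_stage,
            "recovery_duration_s": grid.recovery_duration,
            "equilibration_tolerance": grid.equilibration_tolerance,
            "equilibration_residual_tol": grid.equilibration_residual_tol,
            "equilibration_max_time_s": grid.equilibration_max_time,
            "irradiation_snapshot_stride": grid.irradiation_snapshot_stride,
            "other_snapshot_stride": grid.other_snapshot_stride,
        },
        "boundary": boundary,
        "geometry": geom,
        "protocols": [{"label": p.label, "dose_Gy": p.dose,
                       "dose_rate_Gy_per_s": p.dose_rate,
                       "let_kev_per_um": p.let_d} for p in protocols],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")
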