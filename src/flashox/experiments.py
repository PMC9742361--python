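"""Paired CONV/UHDR scenario runs, parameter sweeps and the reproduction
suite.

A *scenario pair* is the basic experimental unit: one vessel geometry and
supply, equilibrated once, then irradiated twice from that identical
equilibrium — once at a conventional dose rate (0.5 Gy/s) and once at an
ultra-high dose rate (125 or 285 Gy/s) — so that the per-node FEDMF
isolates the dose-rate effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .geometry import (DiscreteDomain, Geometry1D, Geometry2D, Geometry3D,
                       GridSpec, make_domain_1d, make_domain_2d,
                       make_domain_3d)
from .parameters import (BoundarySupply, HRFParameters, IrradiationProtocol,
                         TissueParameters)
from .radiobiology import (CNEDAccumulator, DoseResponseFields, SummaryMetrics,
                           fedmf, fraction_at_or_above, hypoxic_fraction,
                           mean_oxygen, midpoint_value)
from .solver import (OxygenHistory, OxygenState, STAGE_IRRADIATION,
                     equilibrate, run_protocol)

Geometry = Union[Geometry1D, Geometry2D, Geometry3D]

CONV_DOSE_RATE = 0.5       # Gy/s, conventional reference delivery
UHDR_DOSE_RATE = 125.0     # Gy/s, default ultra-high dose-rate delivery
FEDMF_THRESHOLD = 1.20     # FEDMF at or above this counts as a FLASH effect
HYPOXIC_THRESHOLD = 18.9   # μM


def build_domain(geometry: Geometry, dx: float) -> DiscreteDomain:
    if isinstance(geometry, Geometry1D):
        return make_domain_1d(geometry, dx)
    if isinstance(geometry, Geometry2D):
        return make_domain_2d(geometry, dx)
    if isinstance(geometry, Geometry3D):
        return make_domain_3d(geometry, dx)
    raise TypeError(f"unsupported geometry {type(geometry).__name__}")


@dataclass(frozen=True)
class ScenarioPair:
    """A CONV/UHDR delivery pair sharing geometry, tissue and supply."""

    geometry: Geometry
    conv: IrradiationProtocol
    uhdr: IrradiationProtocol
    tissue: TissueParameters = TissueParameters()
    hrf_params: HRFParameters = HRFParameters()
    grid: GridSpec = GridSpec()

    def __post_init__(self) -> None:
        if self.conv.dose != self.uhdr.dose:
            raise ValueError("paired deliveries must share the total dose")
        if not self.conv.dose_rate < self.uhdr.dose_rate:
            raise ValueError("the CONV dose rate must be below the UHDR one")

    @classmethod
    def standard(cls, geometry: Geometry, dose: float,
                 uhdr_rate: float = UHDR_DOSE_RATE, let_d: float = 1.2,
                 conv_rate: float = CONV_DOSE_RATE,
                 tissue: TissueParameters = TissueParameters(),
                 hrf_params: HRFParameters = HRFParameters(),
                 grid: GridSpec = GridSpec()) -> "ScenarioPair":
        return cls(geometry,
                   IrradiationProtocol(dose, conv_rate, let_d, "conv"),
                   IrradiationProtocol(dose, uhdr_rate, let_d, "uhdr"),
                   tissue, hrf_params, grid)

    def with_transient_supplies(self, alpha: float,
                                tau: float) -> "ScenarioPair":
        """Both deliveries rerun with recruitment transients switched on
        at the start of irradiation (t = 0)."""
        g = self.geometry
        if isinstance(g, Geometry1D):
            g2 = replace(g,
                         left_supply=g.left_supply.with_transient(alpha, tau),
                         right_supply=g.right_supply.with_transient(alpha, tau))
        elif isinstance(g, Geometry3D):
            g2 = replace(g, supply=g.supply.with_transient(alpha, tau))
        else:
            raise TypeError("transient supplies: unsupported geometry")
        return replace(self, geometry=g2)


@dataclass(frozen=True)
class PairResult:
    """Everything a paired run produces."""

    pair: ScenarioPair
    domain: DiscreteDomain
    equilibrium: OxygenState
    conv_history: OxygenHistory
    uhdr_history: OxygenHistory
    fields: DoseResponseFields

    def fedmf_fraction(self, threshold: float = FEDMF_THRESHOLD) -> float:
        return fraction_at_or_above(self.fields.fedmf, threshold, self.domain)

    def summary(self) -> SummaryMetrics:
        return SummaryMetrics(
            hypoxic_fraction=hypoxic_fraction(
                self.equilibrium, self.domain, HYPOXIC_THRESHOLD),
            mean_o=mean_oxygen(self.equilibrium, self.domain),
            fedmf_fraction=self.fedmf_fraction(),
            midpoint_trace=self.uhdr_history.midpoint_trace(self.domain)
            if self.domain.ndim != 2 else None)


def run_pair(pair: ScenarioPair,
             equilibrium: Optional[OxygenState] = None,
             include_recovery: bool = True) -> PairResult:
    """Equilibrate once, deliver both protocols, derive CNED and FEDMF.

    CNED integrals are accumulated online at every solver step; snapshot
    strides only affect what the returned histories retain.
    """
    domain = build_domain(pair.geometry, pair.grid.dx)
    if equilibrium is None:
        equilibrium = equilibrate(domain, pair.tissue, pair.grid, at_time=-1.0)
    histories = {}
    cneds = {}
    for key, protocol in (("conv", pair.conv), ("uhdr", pair.uhdr)):
        acc = CNEDAccumulator(protocol.dose_rate, protocol.let_d,
                              pair.hrf_params)
        histories[key] = run_protocol(
            domain, pair.tissue, protocol, pair.grid, initial=equilibrium,
            irradiation_observer=acc.update,
            include_recovery=include_recovery)
        cneds[key] = (acc.cned if protocol.dose > 0
                      else np.zeros(domain.n_nodes))
    ratio = fedmf(cneds["conv"], cneds["uhdr"])
    fields = DoseResponseFields(cneds["conv"], cneds["uhdr"], ratio,
                                pair.conv.label or "conv",
                                pair.uhdr.label or "uhdr")
    return PairResult(pair, domain, equilibrium,
                      histories["conv"], histories["uhdr"], fields)


def run_transient_bc_study(pair: ScenarioPair, alpha: float,
                           tau: float) -> dict:
    """FEDMF fraction with recruitment transients versus the constant-BC
    baseline of the same pair (both from the identical equilibrium —
    transients only act from t >= 0, so the equilibrium is unchanged)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if not tau > 0:
        raise ValueError("tau must be > 0")
    baseline = run_pair(pair, include_recovery=False)
    transient = run_pair(pair.with_transient_supplies(alpha, tau),
                         equilibrium=baseline.equilibrium,
                         include_recovery=False)
    f_base = baseline.fedmf_fraction()
    f_tr = transient.fedmf_fraction()
    return {"fedmf_fraction": f_tr, "baseline_fraction": f_base,
            "delta": f_tr - f_base, "result": transient}


# -- sweeps ---------------------------------------------------------------

SWEEP_COLUMNS = [
    "spacing_um", "supply_uM", "dose_Gy", "conv_rate_Gy_per_s",
    "uhdr_rate_Gy_per_s", "let_kev_per_um", "pre_hypoxic_fraction",
    "pre_mean_o_uM", "midpoint_o_t0_uM", "midpoint_o_end_conv_uM",
    "midpoint_o_end_uhdr_uM", "cned_over_d_midpoint_conv",
    "cned_over_d_midpoint_uhdr", "fedmf_fraction_1p20",
]


def sweep(spacings: Sequence[float], supplies: Sequence[float],
          doses: Sequence[float], uhdr_rates: Sequence[float],
          lets: Sequence[float],
          tissue: TissueParameters = TissueParameters(),
          hrf_params: HRFParameters = HRFParameters(),
          grid: GridSpec = GridSpec(),
          conv_rate: float = CONV_DOSE_RATE) -> pd.DataFrame:
    """Deterministic Cartesian sweep over 1D scenarios.

    Equilibria are cached per (spacing, supply) so every delivery of a
    given geometry starts from the identical state.  Rows follow the
    iteration order spacing > supply > dose > uhdr_rate > LET.
    """
    for name, seq in (("spacings", spacings), ("supplies", supplies),
                      ("doses", doses), ("uhdr_rates", uhdr_rates),
                      ("lets", lets)):
        if len(seq) == 0:
            raise ValueError(f"{name} must be non-empty")
    cache: dict[tuple[float, float], tuple[DiscreteDomain, OxygenState]] = {}
    rows = []
    for spacing in spacings:
        for supply in supplies:
            key = (spacing, supply)
            if key not in cache:
                geom = Geometry1D(spacing, BoundarySupply(supply),
                                  BoundarySupply(supply))
                domain = build_domain(geom, grid.dx)
                cache[key] = (domain,
                              equilibrate(domain, tissue, grid, at_time=-1.0))
            domain, eq = cache[key]
            for dose in doses:
                for rate in uhdr_rates:
                    for let in lets:
                        geom = Geometry1D(spacing, BoundarySupply(supply),
                                          BoundarySupply(supply))
                        pair = ScenarioPair.standard(
                            geom, dose, uhdr_rate=rate, let_d=let,
                            conv_rate=conv_rate, tissue=tissue,
                            hrf_params=hrf_params, grid=grid)
                        try:
                            res = run_pair(pair, equilibrium=eq,
                                           include_recovery=False)
                        except Exception as exc:
                            raise RuntimeError(
                                f"sweep scenario failed: spacing={spacing} μm, "
                                f"supply={supply} μM, dose={dose} Gy, "
                                f"uhdr={rate} Gy/s, LET={let}: {exc}") from exc
                        mid = domain.nearest_node(
                            [(domain.n_nodes - 1) * domain.dx / 2])
                        rows.append({
                            "spacing_um": spacing, "supply_uM": supply,
                            "dose_Gy": dose, "conv_rate_Gy_per_s": conv_rate,
                            "uhdr_rate_Gy_per_s": rate,
                            "let_kev_per_um": let,
                            "pre_hypoxic_fraction": hypoxic_fraction(
                                eq, domain, HYPOXIC_THRESHOLD),
                            "pre_mean_o_uM": mean_oxygen(eq, domain),
                            "midpoint_o_t0_uM": midpoint_value(eq, domain),
                            "midpoint_o_end_conv_uM": midpoint_value(
                                res.conv_history.stage(
                                    STAGE_IRRADIATION).final, domain),
                            "midpoint_o_end_uhdr_uM": midpoint_value(
                                res.uhdr_history.stage(
                                    STAGE_IRRADIATION).final, domain),
                            "cned_over_d_midpoint_conv":
                                float(res.fields.cned_conv[mid]) / dose
                                if dose else 1.0,
                            "cned_over_d_midpoint_uhdr":
                                float(res.fields.cned_uhdr[mid]) / dose
                                if dose else 1.0,
                            "fedmf_fraction_1p20": res.fedmf_fraction(),
                        })
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


# -- reproduction suite ---------------------------------------------------

def _pair_1d(spacing: float, supply: float, dose: float,
             uhdr_rate: float = UHDR_DOSE_RATE, let_d: float = 1.2,
             dx: float = 0.5) -> ScenarioPair:
    geom = Geometry1D(spacing, BoundarySupply(supply), BoundarySupply(supply))
    return ScenarioPair.standard(geom, dose, uhdr_rate=uhdr_rate,
                                 let_d=let_d, grid=GridSpec(dx=dx))


def cuboid_reproduction_pair(center_to_edge: float = 88.4,
                             supply: float = 18.9, dose: float = 15.0,
                             uhdr_rate: float = UHDR_DOSE_RATE,
                             dx: float = 1.25,
                             height: float = 2.5) -> ScenarioPair:
    """The five-vessel cuboid scenario.

    In-plane resolution 1.25 μm resolves the 5 μm vessel radius well
    enough for the FEDMF fraction to be grid-converged; the cuboid height
    is immaterial because the vertical-vessel geometry makes the solution
    exactly invariant along z (a tested property), so only a short stack
    of layers is carried — tall cuboids cost sparse-factorization fill-in
    without changing any metric.
    """
    geom = Geometry3D.from_center_to_edge_distance(
        center_to_edge, height=height, supply=BoundarySupply(supply))
    return ScenarioPair.standard(
        geom, dose, uhdr_rate=uhdr_rate,
        grid=GridSpec(dx=dx, irradiation_snapshot_stride=100,
                      other_snapshot_stride=100))


# One row per benchmark of the reproduction suite: descriptive name,
# reference value, unit, tolerance, and how to compute it.
REFERENCE_SUITE: tuple[dict, ...] = (
    dict(name="fedmf_area_15Gy_175um_18.9uM", reference=61.5, unit="%",
         tol=5.0, kind="1d"),
    dict(name="fedmf_area_8Gy_175um_18.9uM", reference=34.5, unit="%",
         tol=5.0, kind="1d"),
    dict(name="fedmf_area_2Gy_175um_18.9uM", reference=0.0, unit="%",
         tol=5.0, kind="1d"),
    dict(name="fedmf_area_15Gy_50um_5.4uM", reference=55.0, unit="%",
         tol=5.0, kind="1d"),
    dict(name="fedmf_area_15Gy_175um_5.4uM", reference=31.0, unit="%",
         tol=5.0, kind="1d"),
    dict(name="equilibrium_mean_o_250um_50.4uM", reference=24.1, unit="uM",
         tol=0.5, kind="1d"),
    dict(name="midpoint_o_end_uhdr_50um_10.1uM", reference=3.7, unit="uM",
         tol=0.5, kind="1d"),
    dict(name="midpoint_depletion_uhdr_50um_10.1uM", reference=4.3,
         unit="uM", tol=0.5, kind="1d"),
    dict(name="midpoint_o_end_uhdr_50um_50.4uM", reference=43.0, unit="uM",
         tol=0.5, kind="1d"),
    dict(name="fedmf_volume_15Gy_cuboid_88.4um_18.9uM", reference=73.6,
         unit="%", tol=5.0, kind="3d"),
    dict(name="fedmf_area_transient_bc_15Gy_175um_18.9uM", reference=68.5,
         unit="%", tol=5.0, kind="1d"),
    dict(name="fedmf_area_let100_15Gy_175um_18.9uM", reference=22.0,
         unit="%", tol=5.0, kind="1d"),
)


class ReproductionRunner:
    """Computes each benchmark of the reproduction suite from scratch,
    sharing equilibria between scenarios with the same geometry/supply."""

    def __init__(self, tissue: TissueParameters = TissueParameters(),
                 hrf_params: HRFParameters = HRFParameters()):
        self.tissue = tissue
        self.hrf_params = hrf_params
        self._eq_cache: dict = {}
        self._pair_cache: dict = {}

    def _equilibrium(self, pair: ScenarioPair):
        g = pair.geometry
        if isinstance(g, Geometry1D):
            key = ("1d", g.spacing, g.left_supply.base_level,
                   g.right_supply.base_level, pair.grid.dx)
        else:
            key = ("3d", g.cross_section_side, g.height, g.vessel_radius,
                   g.supply.base_level, pair.grid.dx)
        if key not in self._eq_cache:
            domain = build_domain(g, pair.grid.dx)
            self._eq_cache[key] = equilibrate(domain, self.tissue, pair.grid,
                                              at_time=-1.0)
        return self._eq_cache[key]

    def _run(self, pair: ScenarioPair, cache_key) -> PairResult:
        if cache_key not in self._pair_cache:
            pair = replace(pair, tissue=self.tissue,
                           hrf_params=self.hrf_params)
            self._pair_cache[cache_key] = run_pair(
                pair, equilibrium=self._equilibrium(pair),
                include_recovery=False)
        return self._pair_cache[cache_key]

    def _pct(self, x: float) -> float:
        return 100.0 * x

    def compute(self, name: str) -> tuple[float, int]:
        """(value, problem size) for one benchmark, on the printed scale."""
        if name == "fedmf_area_15Gy_175um_18.9uM":
            r = self._run(_pair_1d(175, 18.9, 15), ("t", 15))
            return self._pct(r.fedmf_fraction()), _tissue_n(r)
        if name == "fedmf_area_8Gy_175um_18.9uM":
            r = self._run(_pair_1d(175, 18.9, 8), ("t", 8))
            return self._pct(r.fedmf_fraction()), _tissue_n(r)
        if name == "fedmf_area_2Gy_175um_18.9uM":
            r = self._run(_pair_1d(175, 18.9, 2), ("t", 2))
            return self._pct(r.fedmf_fraction()), _tissue_n(r)
        if name == "fedmf_area_15Gy_50um_5.4uM":
            r = self._run(_pair_1d(50, 5.4, 15), ("t4",))
            return self._pct(r.fedmf_fraction()), _tissue_n(r)
        if name == "fedmf_area_15Gy_175um_5.4uM":
            r = self._run(_pair_1d(175, 5.4, 15), ("t5",))
            return self._pct(r.fedmf_fraction()), _tissue_n(r)
        if name == "equilibrium_mean_o_250um_50.4uM":
            pair = _pair_1d(250, 50.4, 15)
            domain = build_domain(pair.geometry, pair.grid.dx)
            eq = self._equilibrium(pair)
            return mean_oxygen(eq, domain), int(domain.tissue_mask.sum())
        if name == "midpoint_o_end_uhdr_50um_10.1uM":
            r = self._run(_pair_1d(50, 10.1, 15), ("t7",))
            return midpoint_value(r.uhdr_history.stage(
                STAGE_IRRADIATION).final, r.domain), _tissue_n(r)
        if name == "midpoint_depletion_uhdr_50um_10.1uM":
            r = self._run(_pair_1d(50, 10.1, 15), ("t7",))
            end = midpoint_value(r.uhdr_history.stage(
                STAGE_IRRADIATION).final, r.domain)
            return midpoint_value(r.equilibrium, r.domain) - end, _tissue_n(r)
        if name == "midpoint_o_end_uhdr_50um_50.4uM":
            r = self._run(_pair_1d(50, 50.4, 15), ("t9",))
            return midpoint_value(r.uhdr_history.stage(
                STAGE_IRRADIATION).final, r.domain), _tissue_n(r)
        if name == "fedmf_volume_15Gy_cuboid_88.4um_18.9uM":
            r = self._run(cuboid_reproduction_pair(), ("t10",))
            return self._pct(r.fedmf_fraction()), _tissue_n(r)
        if name == "fedmf_area_transient_bc_15Gy_175um_18.9uM":
            base = self._run(_pair_1d(175, 18.9, 15), ("t", 15))
            tr = run_pair(
                _pair_1d(175, 18.9, 15).with_transient_supplies(0.2, 10.0),
                equilibrium=base.equilibrium, include_recovery=False)
            return self._pct(tr.fedmf_fraction()), _tissue_n(tr)
        if name == "fedmf_area_let100_15Gy_175um_18.9uM":
            r = self._run(_pair_1d(175, 18.9, 15, let_d=100.0), ("t12",))
            return self._pct(r.fedmf_fraction()), _tissue_n(r)
        raise KeyError(f"unknown benchmark {name!r}")


def _tissue_n(result: PairResult) -> int:
    return int(result.domain.tissue_mask.sum())


def reproduce(out_dir: Optional[str | Path] = None,
              subset: str = "all") -> pd.DataFrame:
    """Run the reproduction suite and tabulate computed vs reference.

    ``subset`` is ``"all"``, ``"1d"`` or ``"3d"``.  Writes ``report.csv``
    and ``report.json`` into ``out_dir`` when given.  The pipeline is
    fully deterministic, so repeated runs are byte-identical.
    """
    if subset not in ("all", "1d", "3d"):
        raise ValueError("subset must be one of: all, 1d, 3d")
    runner = ReproductionRunner()
    rows = []
    for bench in REFERENCE_SUITE:
        if subset != "all" and bench["kind"] != subset:
            continue
        value, n = runner.compute(bench["name"])
        rows.append({
            "benchmark": bench["name"], "kind": bench["kind"],
            "computed": round(value, 4), "reference": bench["reference"],
            "unit": bench["unit"], "tolerance": bench["tol"],
            "passed": bool(abs(value - bench["reference"]) <= bench["tol"]),
            "n": n,
        })
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "report.csv", index=False)
        (out / "report.json").write_text(
            json.dumps(table.to_dict(orient="records"), indent=1) + "\n")
    return table
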