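"""Radiobiological layer: HRF, CNED, FEDMF and summary metrics.

The hypoxia reduction factor (HRF) maps a local oxygen concentration and
a beam LET to the dose ratio, relative to normoxia, that produces the
same survival.  Weighting the delivered dose rate by 1/HRF over the
delivery gives the cumulative normoxic-equivalent dose (CNED); the ratio
of CNEDs between a conventional and an ultra-high dose-rate delivery of
the same physical dose is the FLASH effective-dose-modifying factor
(FEDMF), the quantity this package exists to compute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import DiscreteDomain, default_probe_point
from .parameters import HRFParameters, IrradiationProtocol
from .solver import OxygenHistory, OxygenState, StageResult, STAGE_IRRADIATION


def hrf(o: np.ndarray | float, let_d: float,
        params: HRFParameters = HRFParameters()) -> np.ndarray | float:
    """Hypoxia reduction factor HRF(LET, O).

        HRF = [b (a M + LET^γ) / (a + LET^γ) + O] / (b + O)

    Bounded in [1, M]; decreasing in both O and LET; equals the anoxic
    plateau F(LET) = (a M + LET^γ)/(a + LET^γ) at O = 0 and tends to 1 as
    O → ∞ (normoxia) or LET → ∞ (oxygen-independent direct damage).
    """
    o_arr = np.asarray(o, dtype=float)
    if np.any(o_arr < 0):
        raise ValueError("oxygen concentration must be >= 0")
    if let_d < 0:
        raise ValueError("LET must be >= 0")
    let_pow = let_d ** params.gamma
    plateau = (params.a_let * params.m_max + let_pow) / (params.a_let + let_pow)
    out = (params.b_oxy * plateau + o_arr) / (params.b_oxy + o_arr)
    return out if isinstance(o, np.ndarray) else float(out)


class CNEDAccumulator:
    """Online trapezoidal accumulation of  Ddot * ∫ 1/HRF(O(x,t)) dt.

    Feed consecutive solver states via :meth:`update`; suitable as the
    ``irradiation_observer`` of :func:`flashox.solver.run_protocol`, which
    keeps the quadrature at full step resolution even when history
    snapshots are thinned.
    """

    def __init__(self, dose_rate: float, let_d: float,
                 params: HRFParameters = HRFParameters()):
        self.dose_rate = dose_rate
        self.let_d = let_d
        self.params = params
        self._integral: Optional[np.ndarray] = None

    def update(self, dt: float, o_before: np.ndarray,
               o_after: np.ndarray) -> None:
        contrib = 0.5 * dt * (1.0 / hrf(o_before, self.let_d, self.params)
                              + 1.0 / hrf(o_after, self.let_d, self.params))
        if self._integral is None:
            self._integral = contrib
        else:
            self._integral += contrib

    @property
    def cned(self) -> np.ndarray:
        if self._integral is None:
            raise ValueError("no steps accumulated")
        return self.dose_rate * self._integral


def cned(history: OxygenHistory | StageResult,
         protocol: IrradiationProtocol,
         params: HRFParameters = HRFParameters()) -> np.ndarray:
    """Per-node cumulative normoxic-equivalent dose, Gy.

    Trapezoidal time integral of ``dose_rate / HRF(O(x, t), LET)`` over
    the stored irradiation-stage snapshots.  Each value lies in (0, D]
    since HRF >= 1.  For the degenerate zero-dose protocol the result is
    identically zero.
    """
    stage = history.stage(STAGE_IRRADIATION) if isinstance(
        history, OxygenHistory) else history
    if stage.stage != STAGE_IRRADIATION:
        raise ValueError("CNED requires the irradiation stage")
    if protocol.dose == 0.0:
        return np.zeros(stage.values.shape[1])
    if len(stage.times) < 2:
        raise ValueError("irradiation stage must hold at least 2 snapshots")
    inv = 1.0 / hrf(stage.values, protocol.let_d, params)
    return protocol.dose_rate * np.trapezoid(inv, stage.times, axis=0)


def fedmf(cned_conv: np.ndarray, cned_uhdr: np.ndarray) -> np.ndarray:
    """FLASH effective-dose-modifying factor: CNED_CONV / CNED_UHDR.

    For the degenerate zero-dose pair (both CNEDs identically zero) the
    factor is defined as 1, the limit of equal deliveries.
    """
    cned_conv = np.asarray(cned_conv, dtype=float)
    cned_uhdr = np.asarray(cned_uhdr, dtype=float)
    if cned_conv.shape != cned_uhdr.shape:
        raise ValueError("CNED fields must share a domain")
    if np.all(cned_conv == 0.0) and np.all(cned_uhdr == 0.0):
        return np.ones_like(cned_conv)
    if np.any(cned_uhdr <= 0.0):
        raise ValueError("UHDR CNED must be positive at every node")
    return cned_conv / cned_uhdr


def fraction_at_or_above(field: np.ndarray, threshold: float,
                         domain: DiscreteDomain) -> float:
    """Fraction of tissue (non-vessel) nodes with ``field >= threshold``.

    Vessel nodes are excluded from both numerator and denominator; on a
    uniform grid the node-count fraction approximates the volume (or
    length) fraction of the inter-vessel space.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    tissue = domain.tissue_mask
    if not tissue.any():
        raise ValueError("domain has no tissue node")
    return float(np.mean(np.asarray(field)[tissue] >= threshold))


def hypoxic_fraction(state: OxygenState | np.ndarray, domain: DiscreteDomain,
                     threshold: float = 18.9) -> float:
    """Fraction of tissue nodes with O strictly below the hypoxic threshold."""
    values = state.values if isinstance(state, OxygenState) else np.asarray(state)
    return 1.0 - fraction_at_or_above(values, threshold, domain)


def mean_oxygen(state: OxygenState | np.ndarray,
                domain: DiscreteDomain) -> float:
    """Mean oxygen concentration over tissue nodes, μM."""
    values = state.values if isinstance(state, OxygenState) else np.asarray(state)
    return float(np.mean(values[domain.tissue_mask]))


def midpoint_value(state: OxygenState | np.ndarray, domain: DiscreteDomain,
                   point: Optional[Sequence[float]] = None) -> float:
    """O at the node nearest the inter-vessel midpoint (or a given probe).

    In 3D the default probe is midway between the center vessel and one
    edge vessel at half the cuboid height; in 2D an explicit probe
    coordinate is required.
    """
    values = state.values if isinstance(state, OxygenState) else np.asarray(state)
    idx = domain.nearest_node(
        default_probe_point(domain) if point is None else point)
    return float(values[idx])


@dataclass(frozen=True)
class DoseResponseFields:
    """Per-node CNED fields of a paired delivery and their FEDMF ratio."""

    cned_conv: np.ndarray
    cned_uhdr: np.ndarray
    fedmf: np.ndarray
    conv_label: str = "conv"
    uhdr_label: str = "uhdr"


@dataclass(frozen=True)
class SummaryMetrics:
    """Headline scalars of one scenario."""

    hypoxic_fraction: float
    mean_o: float
    fedmf_fraction: float
    midpoint_trace: tuple[np.ndarray, np.ndarray] | None = None
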