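"""Physical parameters of the oxygen-transport and radiobiology model.

Canonical unit system throughout the package: length in μm, time in s,
concentration in μM, dose in Gy.  Everything stored on these dataclasses is
already converted; :mod:`flashox.config` does the (single) unit conversion
at load time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class InvalidParameterError(ValueError):
    """A physical parameter violates its admissible range."""


@dataclass(frozen=True)
class TissueParameters:
    """Rate constants of the oxygen reaction-diffusion equation.

    The governing PDE for the tissue oxygen concentration ``O`` (μM) is

        dO/dt = -K1 * Ddot * O/(O + l)  -  K2 * O/(O + lam)  +  K3 * lap(O)

    with a radiolytic depletion term proportional to the dose rate ``Ddot``
    (saturating G-value ``K1``), Michaelis-Menten metabolic consumption
    (maximal rate ``K2``, Michaelis constant ``lam``) and Fickian diffusion
    (coefficient ``K3``).

    Attributes
    ----------
    k1_depletion:
        Radiolytic oxygen depletion G-value, μM/Gy.
    l_depletion:
        Low-oxygen saturation constant of the radiolytic term, μM.
    k2_metabolism:
        Maximal metabolic consumption rate, μM/s.
    lambda_metabolism:
        Michaelis constant of metabolic consumption, μM.
    k3_diffusion:
        Oxygen diffusion coefficient, μm²/s.  A value of 0 disables
        diffusion entirely and reduces the PDE to the well-mixed reaction
        ODE (used for solver verification against an independent
        integrator).
    """

    k1_depletion: float = 0.5
    l_depletion: float = 0.29
    k2_metabolism: float = 18.9
    lambda_metabolism: float = 3.15
    k3_diffusion: float = 2000.0

    def __post_init__(self) -> None:
        for name in ("k1_depletion", "l_depletion", "k2_metabolism",
                     "lambda_metabolism", "k3_diffusion"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InvalidParameterError(
                    f"{name} must be finite and >= 0, got {v!r}")


@dataclass(frozen=True)
class IrradiationProtocol:
    """A constant-dose-rate delivery: total dose, dose rate and LET.

    ``duration`` is derived as ``dose / dose_rate`` (s).  The dose rate is
    applied as a step function in time: zero before the delivery starts,
    ``dose_rate`` during ``[0, duration]``, zero afterwards.
    """

    dose: float
    dose_rate: float
    let_d: float = 1.2
    label: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.dose) or self.dose < 0:
            raise InvalidParameterError(f"dose must be >= 0, got {self.dose!r}")
        if not math.isfinite(self.dose_rate) or self.dose_rate <= 0:
            raise InvalidParameterError(
                f"dose_rate must be > 0, got {self.dose_rate!r}")
        if not math.isfinite(self.let_d) or self.let_d < 0:
            raise InvalidParameterError(
                f"let_d must be >= 0, got {self.let_d!r}")

    @property
    def duration(self) -> float:
        """Delivery duration T = D / Ddot, in seconds."""
        return self.dose / self.dose_rate


@dataclass(frozen=True)
class BoundarySupply:
    """Oxygen level imposed at a vessel wall (Dirichlet boundary value).

    The supply is either constant at ``base_level`` or, when ``transient``
    is set, rises from ``onset`` following a stress-induced functional
    recruitment profile

        O_v(t) = base_level * (1 + alpha * erf(2 (t - onset) / tau))

    which saturates at ``base_level * (1 + alpha)`` on the recruitment
    time scale ``tau``.
    """

    base_level: float
    transient: bool = False
    alpha: float = 0.0
    tau: float = 10.0
    onset: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.base_level) or self.base_level < 0:
            raise InvalidParameterError(
                f"base_level must be >= 0, got {self.base_level!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise InvalidParameterError(
                f"alpha must be in [0, 1], got {self.alpha!r}")
        if self.transient and not self.tau > 0:
            raise InvalidParameterError(
                f"tau must be > 0 for a transient supply, got {self.tau!r}")

    def value_at(self, t: float) -> float:
        """Supply value at time ``t`` (s); constant before ``onset``."""
        if not self.transient or t < self.onset:
            return self.base_level
        return self.base_level * (
            1.0 + self.alpha * math.erf(2.0 * (t - self.onset) / self.tau))

    def with_transient(self, alpha: float, tau: float,
                       onset: float = 0.0) -> "BoundarySupply":
        """A copy of this supply with a recruitment transient attached."""
        return BoundarySupply(self.base_level, transient=True,
                              alpha=alpha, tau=tau, onset=onset)


@dataclass(frozen=True)
class HRFParameters:
    """Constants of the hypoxia reduction factor HRF(LET, O).

    HRF(LET, O) = [b (a M + LET^gamma) / (a + LET^gamma) + O] / (b + O)

    ``m_max`` is the anoxic, low-LET maximum (~3 for the cell-survival data
    this parameterization was fitted to); ``gamma`` and ``a_let`` control
    the decline of the oxygen effect at high LET; ``b_oxy`` is the oxygen
    concentration scale of the transition from hypoxic to normoxic
    response.
    """

    m_max: float = 3.0
    gamma: float = 3.0
    a_let: float = 8.27e5
    b_oxy: float = 2.4

    def __post_init__(self) -> None:
        if self.m_max < 1.0:
            raise InvalidParameterError(
                f"m_max must be >= 1 so that HRF >= 1, got {self.m_max!r}")
        if self.a_let <= 0 or self.b_oxy <= 0:
            raise InvalidParameterError("a_let and b_oxy must be > 0")
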