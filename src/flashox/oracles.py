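"""Independent verification oracles for the PDE solver.

These deliberately avoid the finite-difference machinery in
:mod:`flashox.solver`: one is a closed form, the other an adaptive ODE
integration.  They exist so the solver can be checked against something
it does not share code with.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .parameters import IrradiationProtocol, TissueParameters


class OracleDomainError(ValueError):
    """The oracle's validity precondition does not hold."""


def steady_state_parabola_oracle(params: TissueParameters, spacing: float,
                                 o_v: float,
                                 n_points: int = 101) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form equilibrium profile in the constant-consumption limit.

    When oxygen stays well above the Michaelis constant λ everywhere, the
    metabolic term is approximately the constant K2 and the no-radiation
    steady state of the transport equation between two vessels at O_v is
    the parabola

        O(x) = O_v - (K2 / 2 K3) x (spacing - x).

    Returns ``(x, O)``.  Refuses (raises :class:`OracleDomainError`) when
    the predicted minimum is not well above λ, because the closed form is
    invalid once a hypoxic core forms.
    """
    k2, k3, lam = params.k2_metabolism, params.k3_diffusion, params.lambda_metabolism
    dip = k2 * spacing**2 / (8.0 * k3)
    if o_v - dip < 5.0 * lam:
        raise OracleDomainError(
            f"constant-consumption approximation invalid: predicted midpoint "
            f"{o_v - dip:.3g} μM is not well above λ = {lam} μM")
    x = np.linspace(0.0, spacing, n_points)
    return x, o_v - (k2 / (2.0 * k3)) * x * (spacing - x)


def well_mixed_ode_oracle(params: TissueParameters,
                          protocol: IrradiationProtocol, o0: float,
                          t_eval: np.ndarray | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """High-accuracy reaction-only time course (diffusion absent).

    Integrates  dO/dt = -K1 Ddot O/(O+l) - K2 O/(O+λ)  over the delivery
    [0, T] with an adaptive stiff integrator at rtol 1e-9, for validating
    the PDE stepper in the K3 = 0 limit.  Returns ``(t, O)``.
    """
    if o0 < 0:
        raise ValueError("initial oxygen must be >= 0")
    T = protocol.duration
    if t_eval is None:
        t_eval = np.linspace(0.0, T, 201)

    def rhs(t, y):
        o = max(y[0], 0.0)
        return [-params.k1_depletion * protocol.dose_rate * o / (o + params.l_depletion)
                - params.k2_metabolism * o / (o + params.lambda_metabolism)]

    sol = solve_ivp(rhs, (0.0, T), [o0], method="LSODA",
                    t_eval=t_eval, rtol=1e-9, atol=1e-12)
    return sol.t, np.clip(sol.y[0], 0.0, None)
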