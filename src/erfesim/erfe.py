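"""Erythroferrone subsystem: circadian baseline plus rHuEPO-driven induction.

Baseline. Circulating baseline ERFE (``A_ERFEB``) follows an indirect
response with a time-dependent (cosinor-forcing) input rate and first-order
elimination ``K_out``:

    k_CINE(t) = K_out*RM + RA*(K_out*cos(w*(t - t_peak)) - w*sin(w*(t - t_peak)))
    dA_ERFEB/dt = k_CINE(t) - K_out * A_ERFEB,        w = 2*pi/24

This forcing is constructed so that the exact solution, once initialized on
the curve, is the cosinor ``A_ERFEB(t) = RM + RA*cos(w*(t - t_peak))`` —
mesor RM, amplitude RA, acrophase t_peak.

Induction. rHuEPO induces ERFE release from erythroblasts proportionally to
the erythroblast pool ``A_P3`` and a saturable stimulus ``C/(EC50 + C)``,
delayed by two transit compartments; production into and elimination out of
the induced circulating pool are tied to the transit rate (k_in = k_el =
k_tr), giving a four-stage linear chain at rate ``K_tr`` driven by

    drive(t) = E_max * A_P3(t) * C_EPO(t) / (EC50 + C_EPO(t)).

Observed ERFE is the sum of the baseline pool and the induced circulating
pool.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .params import ParameterSet

__all__ = [
    "OMEGA",
    "circadian_input_rate",
    "circadian_baseline",
    "erfe_induction_rhs",
    "observed_erfe",
]

#: angular frequency of the 24-h rhythm, rad/h
OMEGA = 2.0 * math.pi / 24.0


def circadian_input_rate(t, params: ParameterSet):
    """Time-dependent production rate k_CINE(t) of baseline ERFE (ng/mL/h)."""
    if params.k_out <= 0:
        raise ValueError("K_out must be > 0")
    phase = OMEGA * (np.asarray(t, dtype=float) - params.t_peak)
    return params.k_out * params.rm + params.ra * (
        params.k_out * np.cos(phase) - OMEGA * np.sin(phase)
    )


def circadian_baseline(t, params: ParameterSet):
    """Analytic cosinor solution RM + RA*cos(w*(t - t_peak)) (ng/mL)."""
    return params.rm + params.ra * np.cos(OMEGA * (np.asarray(t, dtype=float) - params.t_peak))


def erfe_induction_rhs(
    state: Sequence[float], p3: float, cepo: float, params: ParameterSet
) -> np.ndarray:
    """Derivative of the induction chain [A_ERFER, A_Tran1, A_Tran2, A_ERFEI].

    ``drive = E_max * p3 * cepo / (EC50 + cepo)``; at ``cepo = EC50`` the
    drive is half-maximal, and at ``cepo = 0`` the chain decays to zero.
    """
    if params.ec50 <= 0:
        raise ValueError("EC50 must be > 0")
    if p3 < 0 or cepo < 0:
        raise ValueError("p3 and cepo must be >= 0")
    er, t1, t2, ei = (float(x) for x in state)
    k = params.k_tr
    drive = params.emax * p3 * cepo / (params.ec50 + cepo) if cepo > 0 else 0.0
    return np.array([k * (drive - er), k * (er - t1), k * (t1 - t2), k * (t2 - ei)])


def observed_erfe(state: Sequence[float]) -> float:
    """Circulating ERFE (ng/mL): baseline pool + induced pool.

    ``state`` is [A_ERFEB, A_ERFER, A_Tran1, A_Tran2, A_ERFEI] (the ERFE
    block of the full state vector).
    """
    return float(state[0]) + float(state[4])
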