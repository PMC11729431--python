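"""Erythropoiesis dynamics: CKD lifespan model and CIA transit model.

Two structurally different models of precursor proliferation and maturation
feed the shared red-cell observables:

CKD (lifespan/amplification). Cells entering stage *k* leave it exactly one
precursor lifespan ``T`` later; amplification factors AMPN (CFU-E per BFU-E)
and AMPC (erythroblasts per CFU-E) scale the flux between stages, and red
cells survive ``T_RBC`` hours. Stage outflows are therefore the production
function evaluated at lagged times — a delay system solved by the method of
steps with a dense production history (see :mod:`erfesim.engine`). Production
is stimulated linearly by rHuEPO concentration and inhibited by circulating
RBC through a power feedback:

    prod(t) = K_IN0 * (RBC0 / RBC(t))**gamma * (1 + K_EPO * C_EPO(t))

with ``K_IN0 = RBC0 / (AMPN*AMPC*T_RBC)`` derived so that the undosed system
is stationary at RBC0.

CIA (proliferation/transit). Self-renewing precursors (``A_P1``) feed three
transit compartments and the circulating pool, all at the shared rate
``k_prol = k_circ = k_tr = (N+1)/MTT``. Proliferation is inhibited by
carboplatin exposure through ``(1 - K_carb * C_carb)`` — deliberately not
clamped at zero, so intense exposure produces net cell kill — and modulated
by the same RBC power feedback, which generates the post-nadir rebound.

Hemoglobin is algebraic throughout: ``HGB = RBC * MCH / 10`` (g/dL).

The functions here are the readable reference algebra; the simulation engine
runs numerically identical compiled kernels (:mod:`erfesim._kernels`).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .params import ParameterSet

__all__ = ["ckd_production_rate", "ckd_rhs", "cia_rhs", "hgb_from_rbc"]


def hgb_from_rbc(rbc, mch: float):
    """Hemoglobin g/dL from RBC count (10^12/L) and MCH (pg/cell)."""
    return np.asarray(rbc) * mch / 10.0


def ckd_production_rate(t: float, rbc: float, cepo: float, params: ParameterSet) -> float:
    """Precursor production rate with RBC feedback and rHuEPO stimulation.

    Returns ``K_IN0`` exactly at the undosed baseline (rbc=RBC0, cepo=0).
    """
    if rbc <= 0:
        raise ValueError(f"RBC state must be > 0, got {rbc}")
    return (
        params.k_in0
        * (params.rbc0 / rbc) ** params.gamma
        * (1.0 + params.k_epo * cepo)
    )


def ckd_rhs(
    t: float,
    state: Sequence[float],
    history: Callable[[float], float],
    cepo: Callable[[float], float],
    params: ParameterSet,
) -> np.ndarray:
    """Reference CKD erythroid derivative (states [P1, P2, P3, P4, RBC]).

    ``history(s)`` must return the production rate at any past time
    ``s <= t`` (constant ``K_IN0`` before the first dose); ``cepo(s)`` the
    rHuEPO concentration. Stage-k outflow equals the amplified production at
    ``t - k*T``; RBC outflow is the inflow delayed by ``T_RBC``.
    """
    T, amp = params.t_prec, params.ampn * params.ampc
    prod_now = ckd_production_rate(t, float(state[4]), float(cepo(t)), params)
    lag = [history(t - k * T) for k in (1, 2, 3, 4)]
    lag_rbc = history(t - 4 * T - params.t_rbc)
    return np.array(
        [
            prod_now - lag[0],
            params.ampn * (lag[0] - lag[1]),
            amp * (lag[1] - lag[2]),
            amp * (lag[2] - lag[3]),
            amp * (lag[3] - lag_rbc),
        ]
    )


def cia_rhs(
    t: float,
    state: Sequence[float],
    ccarb: float,
    params: ParameterSet,
    cepo: float = 0.0,
) -> np.ndarray:
    """Reference CIA erythroid derivative (states [P1, P2, P3, P4, RBC]).

    With ``ccarb = 0`` and the state pinned at RBC0 the derivative is
    identically zero. ``(1 - K_carb*C)`` is not clamped; values below -1
    (strong inversion) are computed as-is.
    """
    p1, p2, p3, p4, rbc = (float(x) for x in state)
    if rbc <= 0:
        raise ValueError(f"RBC state must be > 0, got {rbc}")
    k = params.k_stage
    prolif = (
        k
        * p1
        * (1.0 - params.k_carb * ccarb)
        * (1.0 + params.k_epo * cepo)
        * (params.rbc0 / rbc) ** params.gamma
    )
    return np.array(
        [
            prolif - k * p1,
            k * (p1 - p2),
            k * (p2 - p3),
            k * (p3 - p4),
            k * p4 - k * rbc,
        ]
    )
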