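"""Closed drug-kinetics subsystem.

rHuEPO: two-compartment model with parallel linear and Michaelis-Menten
elimination from the central compartment. The saturable term operates on the
central *concentration* ``C = A1 / Vc`` (mIU/mL), so ``Km`` is directly
comparable to the ERFE-induction ``EC50``. Carboplatin: three-compartment
mammillary model with linear elimination from the central compartment.

Doses are instantaneous i.v. boluses added to the central amount at the event
time. :func:`solve_pk_profile` integrates a full dosing schedule piecewise
between bolus times and returns the central concentration sampled on a fine
grid, which the PD engine consumes by linear interpolation (the grid is fixed,
so generation and fitting see the identical exposure function).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = ["rhuepo_rhs", "carboplatin_rhs", "PkProfile", "solve_pk_profile"]


def rhuepo_rhs(t: float, state: Sequence[float], pk: Mapping[str, float]) -> np.ndarray:
    """Derivative of [A1, A2] (IU/kg) for the rHuEPO model.

    Elimination from central: ``kel*A1 + vmax*C/(km + C)`` with
    ``C = A1/vc``; first-order exchange ``kpt``/``ktp`` with the peripheral
    compartment. At the empty state the derivative is zero.
    """
    if pk["km"] <= 0:
        raise ValueError("rHuEPO Km must be > 0")
    a1, a2 = state
    c = a1 / pk["vc"]
    nonlinear = pk["vmax"] * c / (pk["km"] + c)
    da1 = -pk["kel"] * a1 - nonlinear - pk["kpt"] * a1 + pk["ktp"] * a2
    da2 = pk["kpt"] * a1 - pk["ktp"] * a2
    return np.array([da1, da2])


def carboplatin_rhs(t: float, state: Sequence[float], pk: Mapping[str, float]) -> np.ndarray:
    """Derivative of [A1, A2, A3] (mg/kg) for the linear carboplatin model."""
    a1, a2, a3 = state
    da1 = (
        -pk["kel"] * a1
        - pk["k12"] * a1
        + pk["k21"] * a2
        - pk["k13"] * a1
        + pk["k31"] * a3
    )
    da2 = pk["k12"] * a1 - pk["k21"] * a2
    da3 = pk["k13"] * a1 - pk["k31"] * a3
    return np.array([da1, da2, da3])


@dataclass(frozen=True)
class PkProfile:
    """Central concentration of one drug on a fine time grid.

    ``t``/``c`` are interpolation arrays covering [0, t_end]; ``conc``
    evaluates by linear interpolation (vectorized).
    """

    drug: str
    t: np.ndarray
    c: np.ndarray

    def conc(self, times) -> np.ndarray:
        return np.interp(times, self.t, self.c)

    @classmethod
    def zero(cls, drug: str, t_end: float) -> "PkProfile":
        return cls(drug, np.array([0.0, max(t_end, 1.0)]), np.zeros(2))


def solve_pk_profile(
    drug: str,
    doses: Sequence[tuple[float, float]],
    t_end: float,
    pk_config: Mapping,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    grid_step: float = 0.05,
) -> PkProfile:
    """Integrate a bolus schedule and sample central concentration.

    ``doses`` is a sequence of (time, amount) pairs; amounts are IU/kg for
    rHuEPO, mg/kg for carboplatin. Concentration jumps at dose times are
    represented by a duplicated grid point offset by 1e-9 h.
    """
    if drug == "rHuEPO":
        pk = pk_config["rhuepo"]
        rhs = lambda t, y: rhuepo_rhs(t, y, pk)
        nstate = 2
    elif drug == "carboplatin":
        pk = pk_config["carboplatin"]
        rhs = lambda t, y: carboplatin_rhs(t, y, pk)
        nstate = 3
    else:
        raise ValueError(f"unknown drug {drug!r}")
    doses = sorted((float(t), float(a)) for t, a in doses)
    if not doses:
        return PkProfile.zero(drug, t_end)
    if doses[0][0] < 0:
        raise ValueError("dose times must be >= 0")

    vc = pk["vc"]
    ts: list[np.ndarray] = []
    cs: list[np.ndarray] = []
    y = np.zeros(nstate)
    boundaries = [t for t, _ in doses] + [float(t_end)]
    if boundaries[0] > 0.0:
        ts.append(np.array([0.0, boundaries[0] - 1e-9]))
        cs.append(np.zeros(2))
    idx = 0
    for (t_dose, amt) in doses:
        y = y.copy()
        y[0] += amt
        seg_end = min(
            [b for b in boundaries if b > t_dose] + [float(t_end)]
        )
        seg_end = max(seg_end, t_dose)
        if seg_end <= t_dose + 1e-12:
            ts.append(np.array([t_dose]))
            cs.append(np.array([y[0] / vc]))
            continue
        n = max(int(np.ceil((seg_end - t_dose) / grid_step)), 2)
        t_eval = np.linspace(t_dose, seg_end, n + 1)
        sol = solve_ivp(
            rhs, (t_dose, seg_end), y, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol
        )
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"PK integration failed for {drug}: {sol.message}")
        seg_t = sol.t.copy()
        seg_t[0] += 1e-9  # post-dose value, keep grid strictly increasing
        seg_t[-1] -= 1e-9 if seg_end in dict(doses) else 0.0
        ts.append(seg_t)
        cs.append(sol.y[0] / vc)
        y = sol.y[:, -1]
    t_all = np.concatenate(ts)
    c_all = np.concatenate(cs)
    keep = np.concatenate([[True], np.diff(t_all) > 0])
    return PkProfile(drug, t_all[keep], c_all[keep])
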