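"""Numba-compiled right-hand sides for the coupled PD systems.

These kernels are the hot path of the simulation engine. Readable reference
implementations of the same algebra live in :mod:`erfesim.erythroid` and
:mod:`erfesim.erfe`; a regression test asserts kernel/reference agreement at
random states.

State layout (both models), length 10:
    0..4  erythroid: A_P1, A_P2, A_P3, A_P4, A_RBC
    5     A_ERFEB   circadian baseline ERFE pool (ng/mL)
    6..9  induction chain: A_ERFER, A_Tran1, A_Tran2, A_ERFEI

Exposure enters through (t, c) interpolation arrays produced by
:mod:`erfesim.pk`; the CKD delayed production history enters as (t, prod)
arrays maintained by the method-of-steps driver (pre-experiment history is
the constant baseline rate K_IN0, encoded as s <= 0).
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWO_PI_OVER_24 = 2.0 * np.pi / 24.0

# constant-vector layouts
# ckd: [k_in0, rbc0, gamma, k_epo, t_prec, ampn, ampc, t_rbc,
#       k_out, rm, ra, t_peak, emax, ec50, k_tr, p3_scale, n_chain]
# cia: [k_stage, k_carb, rbc0, gamma, k_epo,
#       k_out, rm, ra, t_peak, emax, ec50, k_tr, p3_scale, n_chain]


@njit(cache=True)
def _erfe_rates(t, y, cepo, p3, k_out, rm, ra, t_peak, emax, ec50, k_tr, p3_scale, n_chain, dy):
    """Fill dy[5:10] with circadian-baseline and induction-chain rates."""
    w = TWO_PI_OVER_24
    k_cine = k_out * rm + ra * (k_out * np.cos(w * (t - t_peak)) - w * np.sin(w * (t - t_peak)))
    dy[5] = k_cine - k_out * y[5]
    if cepo > 0.0:
        drive = emax * (p3_scale * p3) * cepo / (ec50 + cepo)
    else:
        drive = 0.0
    if n_chain >= 4.0:
        dy[6] = k_tr * (drive - y[6])
        dy[7] = k_tr * (y[6] - y[7])
        dy[8] = k_tr * (y[7] - y[8])
        dy[9] = k_tr * (y[8] - y[9])
    else:  # reduced chain (no transit compartments): induction -> circulation
        dy[6] = k_tr * (drive - y[6])
        dy[7] = 0.0
        dy[8] = 0.0
        dy[9] = k_tr * (y[6] - y[9])


@njit(cache=True)
def _prod_lag(s, k_in0, hist_t, hist_p):
    if s <= 0.0:
        return k_in0
    return np.interp(s, hist_t, hist_p)


@njit(cache=True)
def ckd_rhs(t, y, c, pk_t, pk_c, hist_t, hist_p):
    k_in0 = c[0]
    rbc0 = c[1]
    gamma = c[2]
    k_epo = c[3]
    t_prec = c[4]
    ampn = c[5]
    ampc = c[6]
    t_rbc = c[7]

    cepo = np.interp(t, pk_t, pk_c)
    rbc = y[4]
    if rbc < 1e-12:
        rbc = 1e-12
    prod_now = k_in0 * (rbc0 / rbc) ** gamma * (1.0 + k_epo * cepo)

    p1 = _prod_lag(t - t_prec, k_in0, hist_t, hist_p)
    p2 = _prod_lag(t - 2.0 * t_prec, k_in0, hist_t, hist_p)
    p3 = _prod_lag(t - 3.0 * t_prec, k_in0, hist_t, hist_p)
    p4 = _prod_lag(t - 4.0 * t_prec, k_in0, hist_t, hist_p)
    prbc = _prod_lag(t - 4.0 * t_prec - t_rbc, k_in0, hist_t, hist_p)

    amp = ampn * ampc
    dy = np.empty(10)
    dy[0] = prod_now - p1
    dy[1] = ampn * (p1 - p2)
    dy[2] = amp * (p2 - p3)
    dy[3] = amp * (p3 - p4)
    dy[4] = amp * (p4 - prbc)
    _erfe_rates(t, y, cepo, y[2], c[8], c[9], c[10], c[11], c[12], c[13], c[14], c[15], c[16], dy)
    return dy


@njit(cache=True)
def cia_rhs(t, y, c, pkepo_t, pkepo_c, pkcarb_t, pkcarb_c):
    k = c[0]
    k_carb = c[1]
    rbc0 = c[2]
    gamma = c[3]
    k_epo = c[4]

    cepo = np.interp(t, pkepo_t, pkepo_c)
    ccarb = np.interp(t, pkcarb_t, pkcarb_c)
    rbc = y[4]
    if rbc < 1e-12:
        rbc = 1e-12
    # proliferation with carboplatin inhibition (un-clamped: strong exposure
    # drives net kill), RBC feedback, optional direct EPO stimulation
    prolif = (
        k
        * y[0]
        * (1.0 - k_carb * ccarb)
        * (1.0 + k_epo * cepo)
        * (rbc0 / rbc) ** gamma
    )
    dy = np.empty(10)
    dy[0] = prolif - k * y[0]
    dy[1] = k * (y[0] - y[1])
    dy[2] = k * (y[1] - y[2])
    dy[3] = k * (y[2] - y[3])
    dy[4] = k * y[3] - k * y[4]
    _erfe_rates(t, y, cepo, y[2], c[5], c[6], c[7], c[8], c[9], c[10], c[11], c[12], c[13], dy)
    return dy
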