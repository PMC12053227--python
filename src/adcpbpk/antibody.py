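"""Whole-body disposition of the (total) antibody component of the ADC.

Per organ the antibody occupies four states: vascular plasma, endosomal
FcRn-unbound, endosomal FcRn-bound, and interstitial.  Transport processes:

* convection with plasma flow through the anatomical circulation;
* transcapillary filtration ``L (1 - sigma_v) C_v`` into the interstitium and
  lymphatic drainage ``L (1 - sigma_i) C_i`` into a common lymph-node pool
  that returns to blood;
* fluid-phase pinocytosis at rate ``CL_up`` per unit endosomal volume, drawing
  symmetrically from the vascular and interstitial sides;
* kinetic FcRn binding (kon/koff) in the endosome; the bound pool exits at the
  pinocytosis rate, split ``FR`` to the vascular space (recycling) and
  ``1 - FR`` to the interstitium (transcytosis);
* first-order lysosomal degradation of the FcRn-unbound endosomal pool.

Free FcRn is not integrated: receptor conservation is enforced algebraically,
``FcRn_free = FcRn_total - C_endosomal_bound``, so the conservation invariant
holds to machine precision at every solver step.
"""

from __future__ import annotations

import numpy as np

from .parameters import MabParameters
from .topology import PhysArrays


def mab_rhs(arr: PhysArrays, p: MabParameters, Cv, Ceu, Ceb, Ci, Cb, Cln,
            kdeg: float | None = None, validate: bool = False):
    """Time derivatives of the antibody states (concentrations in nM, rates 1/h).

    Parameters
    ----------
    arr : vectorized physiology
    p : antibody parameters
    Cv, Ceu, Ceb, Ci : per-tissue state arrays (vascular, endosomal unbound,
        endosomal FcRn-bound, interstitial)
    Cb, Cln : central blood plasma and lymph-node concentrations
    kdeg : effective degradation rate; defaults to ``p.kdeg_base``
    validate : reject negative state entries (used by the public API; the
        integrator calls the unchecked path)

    Returns
    -------
    (dCv, dCeu, dCeb, dCi, dCb, dCln, deg_flux) where ``deg_flux`` is the
    per-tissue degradation molar flux in nmol/h.
    """
    if validate:
        for name, x in (("Cv", Cv), ("Ceu", Ceu), ("Ceb", Ceb), ("Ci", Ci)):
            if np.any(np.asarray(x) < 0):
                raise ValueError(f"negative antibody state in {name}")
        if Cb < 0 or Cln < 0:
            raise ValueError("negative antibody state in blood/lymph node")
    if kdeg is None:
        kdeg = p.kdeg_base

    arterial = Cv[arr.i_lung]
    inflow = np.empty(arr.n)
    inflow[:] = arr.Q * arterial
    inflow[arr.i_lung] = arr.Q_art_total * Cb
    inflow[arr.i_liver] = (arr.Q[arr.i_liver] * arterial
                           + (arr.Q[arr.i_spl] * Cv[arr.i_spl]).sum())
    outflow = arr.Q_out * Cv
    outflow[arr.i_lung] = arr.Q_art_total * arterial

    filt = arr.L * (1.0 - arr.sv) * Cv          # vascular -> interstitial
    drain = arr.L * (1.0 - arr.si) * Ci         # interstitial -> lymph node
    up_v = p.CL_up * arr.Ve * Cv                # pinocytosis from vascular side
    up_i = p.CL_up * arr.Ve * Ci                # pinocytosis from interstitial side
    exit_b = p.CL_up * arr.Ve * Ceb             # bound pool leaving the endosome

    FcRn_free = arr.phys.FcRn_total - Ceb
    bind = p.kon_FcRn * Ceu * FcRn_free
    unbind = p.koff_FcRn * Ceb

    deg_flux = kdeg * Ceu * arr.Ve              # nmol/h

    dCv = (inflow - outflow - filt - up_v + p.FR * exit_b) / arr.Vp
    dCeu = p.CL_up * (Cv + Ci) - bind + unbind - kdeg * Ceu
    dCeb = bind - unbind - p.CL_up * Ceb
    dCi = (filt + (1.0 - p.FR) * exit_b - drain - up_i) / arr.Vi

    venous = (arr.Q_out[arr.i_direct] * Cv[arr.i_direct]).sum() \
        + arr.Q_out[arr.i_liver] * Cv[arr.i_liver]
    dCb = (venous + arr.L_sum * Cln - arr.Q_art_total * Cb) / arr.Vb
    dCln = (drain.sum() - arr.L_sum * Cln) / arr.Vln
    return dCv, dCeu, dCeb, dCi, dCb, dCln, deg_flux


def total_mab_amount(arr: PhysArrays, Cv, Ceu, Ceb, Ci, Cb, Cln) -> float:
    """Total antibody moles (nmol) across all compartments."""
    return float((Cv * arr.Vp + (Ceu + Ceb) * arr.Ve + Ci * arr.Vi).sum()
                 + Cb * arr.Vb + Cln * arr.Vln)


def mab_steady_ratio_check(result, rel_tol: float = 1e-3):
    """Per-tissue interstitial:vascular concentration ratios near steady state.

    Intended for regression checks of the reflection-coefficient handling in a
    closed system (no degradation, no pinocytosis): the two-flux balance
    ``L (1-sigma_v) C_v = L (1-sigma_i) C_i`` gives a steady ratio
    ``(1-sigma_v)/(1-sigma_i)``, i.e. ``1 - sigma_v`` when ``sigma_i = 0``.

    Returns ``(ratios, at_steady_state)``; the flag is False when the relative
    rate of change of any interstitial concentration still exceeds ``rel_tol``
    per hour at the final time.
    """
    Cv = result.mab_tissue("vascular")[:, -1]
    Ci = result.mab_tissue("interstitial")[:, -1]
    ratios = np.where(Cv > 0, Ci / np.where(Cv > 0, Cv, 1.0), np.nan)

    Ci_prev = result.mab_tissue("interstitial")[:, -2]
    dt_h = (result.t_days[-1] - result.t_days[-2]) * 24.0
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_rate = np.abs(Ci - Ci_prev) / np.where(Ci > 0, Ci, 1.0) / dt_h
    steady = bool(np.all(rel_rate[np.asarray(Ci) > 0] < rel_tol))
    return ratios, steady
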