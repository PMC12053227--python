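"""Whole-body disposition of the unconjugated payload (MMAE).

The payload distributes rapidly among plasma, endothelial and interstitial
water, so those three sub-compartment volumes are lumped into one well-mixed
extracellular pool per organ.  Exchange with blood cells and with the cellular
space is permeability-limited (PS terms) with partition coefficients setting
the equilibrium ratios.  Blood cells travel with regional blood flow using
hematocrit-weighted flow rates.  Hepatic clearance of unbound payload in the
liver extracellular (interstitial-containing) pool is the only elimination
pathway; biliary excretion and P-gp efflux are intentionally absent.
"""

from __future__ import annotations

import numpy as np

from .topology import PhysArrays


def hepatic_clearance_rate(CLint_ml_min_kg: float, fup: float, body_weight_kg: float) -> float:
    """Hepatic clearance (L/h) applied to the liver extracellular concentration.

    ``CLint`` (mL/min/kg) is rescaled to L/h for the species body weight and
    multiplied by the unbound fraction, so the flux is
    ``CL * C_extracellular,liver`` with the protein-binding correction built in.
    """
    if CLint_ml_min_kg < 0 or fup < 0 or body_weight_kg < 0:
        raise ValueError("inputs must be >= 0")
    return CLint_ml_min_kg * body_weight_kg * 60.0 / 1000.0 * fup


def mmae_rhs(arr: PhysArrays, kp, ps_cell, ps_bc, ps_bc_blood, kp_bc, cl_hep,
             Cec, Cbc, Cc, Cbp, Cbbc, src_ec=None, src_cell=None, src_bp=0.0,
             validate: bool = False):
    """Time derivatives of the payload states (nM, 1/h).

    ``src_ec`` / ``src_cell`` are per-tissue molar source rates (nmol/h) from
    deconjugation and degradation; ``src_bp`` feeds the central plasma pool
    (plasma deconjugation).  ``cl_hep`` is the output of
    :func:`hepatic_clearance_rate`.

    Returns ``(dCec, dCbc, dCc, dCbp, dCbbc, elim_flux)`` with the hepatic
    elimination flux in nmol/h.
    """
    if validate:
        for name, x in (("Cec", Cec), ("Cbc", Cbc), ("Cc", Cc)):
            if np.any(np.asarray(x) < 0):
                raise ValueError(f"negative payload state in {name}")
        if Cbp < 0 or Cbbc < 0:
            raise ValueError("negative payload state in blood")
    if src_ec is None:
        src_ec = np.zeros(arr.n)
    if src_cell is None:
        src_cell = np.zeros(arr.n)

    # plasma-borne convection on the lumped extracellular pool
    arterial = Cec[arr.i_lung]
    inflow = arr.Q * arterial
    inflow[arr.i_lung] = arr.Q_art_total * Cbp
    inflow[arr.i_liver] = (arr.Q[arr.i_liver] * arterial
                           + (arr.Q[arr.i_spl] * Cec[arr.i_spl]).sum())
    outflow = arr.Q_out * Cec
    outflow[arr.i_lung] = arr.Q_art_total * arterial

    # blood-cell convection (hematocrit-weighted flows)
    Qbc = arr.Q * arr.bc_ratio
    Qbc_out = arr.Q_out * arr.bc_ratio
    art_bc = Cbc[arr.i_lung]
    inflow_bc = Qbc * art_bc
    inflow_bc[arr.i_lung] = arr.Q_art_total * arr.bc_ratio * Cbbc
    inflow_bc[arr.i_liver] = (Qbc[arr.i_liver] * art_bc
                              + (Qbc[arr.i_spl] * Cbc[arr.i_spl]).sum())
    outflow_bc = Qbc_out * Cbc
    outflow_bc[arr.i_lung] = arr.Q_art_total * arr.bc_ratio * art_bc

    ex_bc = ps_bc * (Cec - Cbc / kp_bc)       # plasma -> blood cells
    ex_cell = ps_cell * (Cec - Cc / kp)       # extracellular -> cellular

    elim = np.zeros(arr.n)
    elim[arr.i_liver] = cl_hep * Cec[arr.i_liver]   # nmol/h

    dCec = (inflow - outflow - ex_bc - ex_cell - elim + src_ec) / arr.Vec
    dCbc = (inflow_bc - outflow_bc + ex_bc) / arr.Vbc
    dCc = (ex_cell + src_cell) / arr.Vc

    ex_bc_central = ps_bc_blood * (Cbp - Cbbc / kp_bc)
    venous = (arr.Q_out[arr.i_direct] * Cec[arr.i_direct]).sum() \
        + arr.Q_out[arr.i_liver] * Cec[arr.i_liver]
    venous_bc = (Qbc_out[arr.i_direct] * Cbc[arr.i_direct]).sum() \
        + Qbc_out[arr.i_liver] * Cbc[arr.i_liver]
    dCbp = (venous - arr.Q_art_total * Cbp - ex_bc_central + src_bp) / arr.Vb
    dCbbc = (venous_bc - arr.Q_art_total * arr.bc_ratio * Cbbc + ex_bc_central) / arr.Vb_bc
    return dCec, dCbc, dCc, dCbp, dCbbc, float(elim[arr.i_liver])


def total_payload_amount(arr: PhysArrays, Cec, Cbc, Cc, Cbp, Cbbc) -> float:
    """Total free-payload moles (nmol) across all compartments."""
    return float((Cec * arr.Vec + Cbc * arr.Vbc + Cc * arr.Vc).sum()
                 + Cbp * arr.Vb + Cbbc * arr.Vb_bc)
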