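"""DAR kinetics and the deconjugation/degradation coupling between the models.

The average drug-to-antibody ratio (DAR) of the circulating ADC declines by
nonspecific deconjugation.  The deconjugation rate constant is an empirical
sigmoidal function of the current DAR,

    k_dec(DAR) = (alpha - (alpha - beta) * DAR^-tau / (F + DAR^-tau)) * SF,

which interpolates between a fast high-DAR asymptote ``alpha`` and a slow
low-DAR asymptote ``beta`` and reproduces the biphasic DAR-versus-time decline
observed across species.  ``SF`` is a species scaling factor obtained by
allometry with exponent -0.25 against the mouse.  The DAR itself follows

    dDAR/dt = -k_dec(DAR) * DAR.

Payload release fluxes: deconjugation releases free payload from every
antibody-containing compartment at rate k_dec * DAR * (mAb amount), and
lysosomal degradation of an ADC molecule releases a number of payloads equal
to the current DAR.
"""

from __future__ import annotations

import numpy as np

from .parameters import DeconjugationParams
from .units import HOURS_PER_DAY


def kdec_of_dar(dar, p: DeconjugationParams):
    """DAR-dependent deconjugation rate constant (1/day).

    Evaluated in the algebraically equivalent form
    ``alpha - (alpha - beta) / (F * DAR^tau + 1)`` which is numerically stable
    for small DAR and returns the continuous limit ``beta * SF`` at DAR = 0.
    Accepts scalars or arrays.
    """
    dar = np.asarray(dar, dtype=float)
    if np.any(dar < 0):
        raise ValueError("DAR must be >= 0")
    k = (p.alpha - (p.alpha - p.beta) / (p.F * dar ** p.tau + 1.0)) * p.SF
    return float(k) if k.ndim == 0 else k


def kdec_of_dar_per_hour(dar, p: DeconjugationParams):
    """k_dec converted to the internal hour-based unit system."""
    return kdec_of_dar(dar, p) / HOURS_PER_DAY


def dar_derivative(dar, p: DeconjugationParams):
    """dDAR/dt (1/day): first-order DAR loss with the DAR-dependent rate."""
    return -kdec_of_dar(dar, p) * np.asarray(dar, dtype=float)


def deconjugation_release_fluxes(mab_amounts_nmol: dict[str, float], dar: float,
                                 p: DeconjugationParams) -> dict[str, float]:
    """Free-payload molar source rates (nmol/h) from deconjugation.

    ``mab_amounts_nmol`` maps compartment labels to antibody molar amounts; each
    compartment releases payload at ``k_dec * DAR * amount``, entering the
    payload compartment of the same tissue (endosomal release is mapped to the
    lumped extracellular pool).
    """
    k = kdec_of_dar_per_hour(dar, p)
    return {name: k * dar * amt for name, amt in mab_amounts_nmol.items()}


def degradation_release_flux(endosomal_unbound_mab_amount_nmol: float,
                             kdeg: float, dar: float) -> float:
    """Payload release rate (nmol/h) from lysosomal ADC degradation.

    Each degraded ADC molecule releases DAR payload molecules into the cellular
    space of the same tissue.
    """
    if endosomal_unbound_mab_amount_nmol < 0 or kdeg < 0 or dar < 0:
        raise ValueError("inputs must be >= 0")
    return kdeg * endosomal_unbound_mab_amount_nmol * dar


def analyte_assembly(mab_plasma_nM, dar, mmae_plasma_nM,
                     mw_mab: float, mw_mmae: float) -> dict:
    """Assemble reported analyte concentrations from molar model outputs.

    Returns total mAb in µg/mL, conjugated MMAE and unconjugated MMAE in
    ng/mL.  Conjugated mAb is not reported separately: the average-DAR
    formulation collapses it onto total mAb.
    """
    mab = np.asarray(mab_plasma_nM, dtype=float)
    mmae = np.asarray(mmae_plasma_nM, dtype=float)
    dar = np.asarray(dar, dtype=float)
    out = {
        "total_mAb_ugml": mab * mw_mab * 1e-6,
        "conjugated_MMAE_ngml": dar * mab * mw_mmae * 1e-3,
        "unconjugated_MMAE_ngml": mmae * mw_mmae * 1e-3,
    }
    if out["total_mAb_ugml"].ndim == 0:
        out = {k: float(v) for k, v in out.items()}
    return out
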