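"""Precomputed array form of the species physiology and circulation topology.

Both the antibody and the payload models share the anatomical wiring: the
central blood pool feeds the lung in series; the lung outflow perfuses all
other organs in parallel; splanchnic organs (spleen, small/large intestine,
pancreas) drain into the liver inflow; everything else returns to the central
pool.  Lymph (antibody only) collects interstitial drainage into a single
lymph-node pool that returns to blood.
"""

from __future__ import annotations

import numpy as np

from .physiology import SpeciesPhysiology, TISSUE_ORDER, SPLANCHNIC
from .parameters import AdcParameterSet


class PhysArrays:
    """Vectorized physiology: volumes, flows and routing index arrays."""

    def __init__(self, phys: SpeciesPhysiology):
        self.phys = phys
        names = list(TISSUE_ORDER)
        self.names = names
        self.n = len(names)
        get = lambda f: np.array([getattr(phys.tissue(t), f) for t in names])
        self.Vp = get("V_plasma")
        self.Vbc = get("V_bloodcell")
        self.Ve = get("V_endosomal")
        self.Vi = get("V_interstitial")
        self.Vc = get("V_cellular")
        self.Q = get("Q_plasma")
        self.L = get("L_lymph")
        self.sv = get("sigma_v")
        self.si = get("sigma_i")

        self.i_lung = names.index("lung")
        self.i_liver = names.index("liver")
        self.i_spl = np.array([names.index(t) for t in SPLANCHNIC])
        # parallel organs returning directly to venous blood (non-lung, non-liver,
        # non-splanchnic)
        excluded = {self.i_lung, self.i_liver, *self.i_spl.tolist()}
        self.i_direct = np.array([i for i in range(self.n) if i not in excluded])

        # venous outflow rate of each organ; liver carries hepatic artery +
        # splanchnic inflows
        self.Q_out = self.Q.copy()
        self.Q_out[self.i_liver] = self.Q[self.i_liver] + self.Q[self.i_spl].sum()
        # arterial supply drawn from the lung outflow (exact, so drug mass is
        # conserved even under a small flow imbalance in the data file)
        self.Q_art_total = self.Q.sum() - self.Q[self.i_lung]
        self.L_sum = self.L.sum()

        hct = phys.hematocrit
        self.bc_ratio = hct / (1.0 - hct)   # blood-cell flow per unit plasma flow
        self.Vb = phys.V_blood_plasma
        self.Vb_bc = phys.V_blood_cell
        self.Vln = phys.V_lymphnode
        self.Vec = self.Vp + self.Ve + self.Vi   # lumped payload extracellular pool

    def payload_arrays(self, params: AdcParameterSet):
        """Per-tissue payload parameter vectors (with optional PS allometry)."""
        p = params.payload
        kp = np.array([p.Kp_tissue[t] for t in self.names])
        ps_cell = np.array([p.PS_cell[t] for t in self.names])
        ps_bc = np.array([p.PS_BC[t] for t in self.names])
        ps_bc_blood = p.PS_BC_blood
        b = p.ps_allometric_exponent
        if b != 0.0:
            scale = (self.phys.body_weight / p.ps_reference_weight) ** b
            ps_cell = ps_cell * scale
            ps_bc = ps_bc * scale
            ps_bc_blood = ps_bc_blood * scale
        return kp, ps_cell, ps_bc, ps_bc_blood
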