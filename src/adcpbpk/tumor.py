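"""Cell-level tumor disposition model.

A single well-mixed tumor of configurable diameter exchanges ADC and free
payload with the central plasma pool (vascular exchange only — tumors lack
functional lymphatic drainage).  Inside the tumor the ADC binds a finite
antigen pool (kon/koff), bound complexes internalize, and internalized ADC is
degraded, releasing DAR-equivalent payload into the intracellular space.
Free payload partitions between the intracellular and extracellular spaces
and equilibrates with plasma.

Antigen bookkeeping: internalization returns the receptor to the free pool
(recycling convention) and antigen synthesis/turnover is off by default, so
``free + bound = antigen_total`` holds exactly.

All rates and the per-IHC-grade antigen concentrations are assumed defaults,
not transcribed values; they are documented in the packaged parameter file
header and in docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: assumed HER2 antigen concentrations (nM, tumor extracellular basis) by IHC grade
IHC_ANTIGEN_NM = {"TNBC": 2.0, "IHC1+": 30.0, "IHC2+": 150.0, "IHC3+": 600.0}


@dataclass
class TumorParams:
    """Tumor geometry, antigen level and cell-level kinetic constants."""

    tumor_diameter: float = 2.5      # cm (T2 category default)
    antigen_total: float = 150.0     # nM (IHC2+ default)
    kon_Ag: float = 0.1              # 1/nM/h
    koff_Ag: float = 0.1             # 1/h
    k_int: float = 0.05              # 1/h internalization of bound complex
    k_deg_tumor: float = 0.1         # 1/h intracellular ADC degradation
    k_vasc_mab: float = 0.03         # 1/h vascular exchange, antibody
    k_vasc_mmae: float = 1.0         # 1/h vascular exchange, payload
    ps_payload: float = 2.0          # 1/h intra/extracellular payload exchange
    Kp_tumor: float = 4.0            # intracellular:extracellular payload partition
    void_fraction: float = 0.24      # extracellular (interstitial) volume fraction

    @classmethod
    def for_grade(cls, grade: str, **kwargs) -> "TumorParams":
        if grade not in IHC_ANTIGEN_NM:
            raise ValueError(f"unknown IHC grade {grade!r}; expected {list(IHC_ANTIGEN_NM)}")
        return cls(antigen_total=IHC_ANTIGEN_NM[grade], **kwargs)

    def validate(self) -> None:
        for f in ("kon_Ag", "koff_Ag", "k_int", "k_deg_tumor", "k_vasc_mab",
                  "k_vasc_mmae", "ps_payload", "antigen_total"):
            if getattr(self, f) < 0:
                raise ValueError(f"TumorParams.{f} must be >= 0")
        if self.tumor_diameter <= 0:
            raise ValueError("tumor_diameter must be positive")
        if not (0.0 < self.void_fraction < 1.0):
            raise ValueError("void_fraction must lie in (0, 1)")

    @property
    def volume_L(self) -> float:
        """Spherical tumor volume (L) from the diameter in cm."""
        return math.pi / 6.0 * self.tumor_diameter ** 3 / 1000.0

    @property
    def V_ex(self) -> float:
        return self.volume_L * self.void_fraction

    @property
    def V_cell(self) -> float:
        return self.volume_L * (1.0 - self.void_fraction)


def receptor_occupancy(result) -> np.ndarray:
    """Fraction of tumor antigen bound to ADC over time (in [0, 1])."""
    if result.tumor is None:
        raise ValueError("simulation was run without a tumor")
    bound = result.tumor_state("adc_bound")
    return bound / result.tumor.antigen_total
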