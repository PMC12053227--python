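"""Parameter containers for the coupled antibody + payload ADC model.

The antibody side carries FcRn binding kinetics, pinocytosis and lysosomal
degradation; the payload side carries plasma protein binding, partition
coefficients and hepatic intrinsic clearance; the coupling block carries the
DAR-dependent deconjugation coefficients and the interspecies scaling rules.
All rate constants live in the internal nM / hour unit system except the
deconjugation coefficients, which are per day as published and converted at
the point of use.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from importlib import resources
from pathlib import Path

import yaml

from .physiology import SPECIES, TISSUE_ORDER, BODY_WEIGHTS, UnsupportedSpeciesError
from .units import MW_MAB, MW_MMAE


@dataclass
class MabParameters:
    """Antibody disposition parameters (shared structure across tissues)."""

    kon_FcRn: float     # 1/nM/h
    koff_FcRn: float    # 1/h
    CL_up: float        # 1/h per unit endosomal volume
    FR: float           # fraction of FcRn-bound mAb recycled to vascular space
    kdeg_base: float    # 1/h, degradation of FcRn-unbound endosomal mAb

    def validate(self) -> None:
        for f in ("kon_FcRn", "koff_FcRn", "CL_up", "kdeg_base"):
            if getattr(self, f) < 0:
                raise ValueError(f"MabParameters.{f} must be >= 0")
        if not (0.0 <= self.FR <= 1.0):
            raise ValueError("MabParameters.FR must lie in [0, 1]")


@dataclass
class PayloadParameters:
    """Unconjugated-payload disposition parameters.

    ``Kp_tissue``, ``PS_cell`` and ``PS_BC`` are per-tissue maps; ``PS_BC_blood``
    is the exchange term of the central blood pool.  PS values are
    species-independent by default; setting ``ps_allometric_exponent`` to 0.75
    or 1 scales them by (body weight / 0.028 kg)^b.
    """

    fup: float                      # unbound fraction in plasma
    Kp_BC: float                    # blood-cell : plasma partition
    CLint: float                    # hepatic intrinsic clearance, mL/min/kg
    Kp_tissue: dict[str, float] = field(default_factory=dict)
    PS_cell: dict[str, float] = field(default_factory=dict)   # L/h
    PS_BC: dict[str, float] = field(default_factory=dict)     # L/h
    PS_BC_blood: float = 0.0                                  # L/h
    ps_allometric_exponent: float = 0.0
    ps_reference_weight: float = 0.028

    def validate(self) -> None:
        if not (0.0 < self.fup <= 1.0):
            raise ValueError("PayloadParameters.fup must lie in (0, 1]")
        if self.Kp_BC < 0 or self.CLint < 0:
            raise ValueError("Kp_BC and CLint must be >= 0")
        for name in TISSUE_ORDER:
            for m, label in ((self.Kp_tissue, "Kp_tissue"), (self.PS_cell, "PS_cell"),
                             (self.PS_BC, "PS_BC")):
                if name not in m:
                    raise ValueError(f"PayloadParameters.{label} missing tissue {name!r}")
                if m[name] < 0:
                    raise ValueError(f"PayloadParameters.{label}[{name!r}] must be >= 0")


@dataclass
class DeconjugationParams:
    """Coefficients of the empirical DAR-dependent deconjugation rate (per day)."""

    alpha: float = 0.0806
    beta: float = 0.0102
    F: float = 0.282
    tau: float = 5.68
    SF: float = 1.0

    def validate(self) -> None:
        if not (self.alpha >= self.beta >= 0.0):
            raise ValueError("require alpha >= beta >= 0")
        if self.F <= 0 or self.tau <= 0:
            raise ValueError("F and tau must be positive")
        if not (0.0 < self.SF <= 1.0):
            raise ValueError("SF must lie in (0, 1]")


@dataclass
class AdcCouplingParams:
    """Conjugation-level constants linking the antibody and payload models."""

    DAR0: float = 4.0
    f_Kdeg: float = 1.0
    MW_mAb: float = MW_MAB
    MW_MMAE: float = MW_MMAE

    def validate(self) -> None:
        if self.DAR0 <= 0:
            raise ValueError("DAR0 must be positive")
        if self.f_Kdeg < 1.0:
            raise ValueError("f_Kdeg must be >= 1")


@dataclass
class AdcParameterSet:
    """Complete drug-parameter bundle for one species."""

    species: str
    mab: MabParameters
    payload: PayloadParameters
    deconjugation: DeconjugationParams
    coupling: AdcCouplingParams

    def validate(self) -> None:
        self.mab.validate()
        self.payload.validate()
        self.deconjugation.validate()
        self.coupling.validate()

    def to_dict(self) -> dict:
        return asdict(self)


def _load_payload_tissue_table(path: Path | None = None):
    if path is None:
        path = Path(str(resources.files("adcpbpk").joinpath("data", "payload_tissue.csv")))
    kp, ps_cell, ps_bc = {}, {}, {}
    ps_bc_blood = 0.0
    header = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cells = [c.strip() for c in line.split(",")]
        if header is None:
            header = cells
            continue
        row = dict(zip(header, cells))
        name = row["tissue"]
        if name == "blood":
            ps_bc_blood = float(row["PS_BC"])
            continue
        kp[name] = float(row["Kp"])
        ps_cell[name] = float(row["PS_cell"])
        ps_bc[name] = float(row["PS_BC"])
    return kp, ps_cell, ps_bc, ps_bc_blood


def allometric_sf(body_weight: float, reference_weight: float = 0.028,
                  exponent: float = -0.25) -> float:
    """Allometric deconjugation scaling factor, SF = (BW / BW_ref)^exponent.

    Returns the raw value; the reporting layer rounds to one decimal to match
    the species values used in the model (1, 0.6, 0.3, 0.1).
    """
    if body_weight <= 0 or reference_weight <= 0:
        raise ValueError("body weights must be positive")
    return (body_weight / reference_weight) ** exponent


def kdeg_for_species(kdeg_mouse: float, f_Kdeg: float) -> float:
    """Species ADC degradation rate: mouse naked-mAb rate times the fold-change."""
    return kdeg_mouse * f_Kdeg


def default_parameters(species: str, source: str | Path | None = None) -> AdcParameterSet:
    """Packaged per-species ADC parameter set (Table-derived values + documented defaults)."""
    if species not in SPECIES:
        raise UnsupportedSpeciesError(
            f"species {species!r} not supported; expected one of {SPECIES}")
    if source is None:
        source = Path(str(resources.files("adcpbpk").joinpath("data", "adc_params.yaml")))
    cfg = yaml.safe_load(Path(source).read_text())
    sp = cfg["species"][species]
    shared = cfg["mab_shared"]
    mab = MabParameters(
        kon_FcRn=float(sp["kon_FcRn"]), koff_FcRn=float(sp["koff_FcRn"]),
        CL_up=float(shared["CL_up"]), FR=float(shared["FR"]),
        kdeg_base=float(shared["kdeg_base"]))
    kp, ps_cell, ps_bc, ps_bc_blood = _load_payload_tissue_table()
    payload = PayloadParameters(
        fup=float(sp["fup"]), Kp_BC=float(sp["Kp_BC"]), CLint=float(sp["CLint"]),
        Kp_tissue=kp, PS_cell=ps_cell, PS_BC=ps_bc, PS_BC_blood=ps_bc_blood)
    dc = cfg["deconjugation"]
    sf = round(allometric_sf(BODY_WEIGHTS[species], float(dc["reference_weight"]),
                             float(dc["exponent"])), 1)
    deconj = DeconjugationParams(alpha=float(dc["alpha"]), beta=float(dc["beta"]),
                                 F=float(dc["F"]), tau=float(dc["tau"]), SF=sf)
    cp = cfg["coupling"]
    coupling = AdcCouplingParams(DAR0=float(cp["DAR0"]), f_Kdeg=float(sp["f_Kdeg"]),
                                 MW_mAb=float(cp["MW_mAb"]), MW_MMAE=float(cp["MW_MMAE"]))
    params = AdcParameterSet(species=species, mab=mab, payload=payload,
                             deconjugation=deconj, coupling=coupling)
    params.validate()
    return params


def with_scaled_kp(params: AdcParameterSet, tissue: str, factor: float) -> AdcParameterSet:
    """Copy of ``params`` with one tissue's cellular partition coefficient scaled."""
    kp = dict(params.payload.Kp_tissue)
    if tissue not in kp:
        raise KeyError(tissue)
    kp[tissue] = kp[tissue] * factor
    return replace(params, payload=replace(params.payload, Kp_tissue=kp))
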