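"""Species physiology registry for the whole-body PBPK models.

Each of the four supported species (mouse, rat, monkey, human) ships with a
tabular parameter file describing the 15 perfused organ compartments plus the
central blood and lymph-node pools.  Every organ is subdivided into plasma,
blood-cell, endosomal, interstitial and cellular sub-compartment volumes, and
carries a plasma flow, a lymph flow and the two reflection coefficients that
govern convective antibody transport.

The splanchnic organs (spleen, small/large intestine, pancreas) drain into the
liver inflow; every other organ is perfused in parallel between the lung (in
series with the central blood pool) and the venous return.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

SPECIES = ("mouse", "rat", "monkey", "human")

#: canonical organ order used for every state vector in the simulator
TISSUE_ORDER = (
    "lung",
    "heart",
    "kidney",
    "muscle",
    "skin",
    "liver",
    "brain",
    "fat",
    "thymus",
    "bone",
    "small_intestine",
    "large_intestine",
    "spleen",
    "pancreas",
    "other",
)

#: organs whose venous outflow drains into the liver inflow
SPLANCHNIC = ("spleen", "small_intestine", "large_intestine", "pancreas")

#: body weights (kg) used throughout the model
BODY_WEIGHTS = {"mouse": 0.028, "rat": 0.28, "monkey": 6.2, "human": 70.0}


class UnsupportedSpeciesError(ValueError):
    """Raised for species outside the mouse/rat/monkey/human set."""


class PhysiologySchemaError(ValueError):
    """Raised when a physiology parameter file is malformed; names the field."""


@dataclass
class TissueSpec:
    """Volumes (L), flows (L/h) and reflection coefficients of one organ."""

    name: str
    V_plasma: float
    V_bloodcell: float
    V_endosomal: float
    V_interstitial: float
    V_cellular: float
    Q_plasma: float
    L_lymph: float
    sigma_v: float
    sigma_i: float

    def violations(self) -> list[str]:
        out = []
        for f in ("V_plasma", "V_bloodcell", "V_endosomal", "V_interstitial",
                  "V_cellular", "Q_plasma", "L_lymph"):
            if getattr(self, f) < 0:
                out.append(f"{self.name}: {f} is negative")
        if self.L_lymph >= self.Q_plasma > 0:
            out.append(f"{self.name}: L_lymph must be < Q_plasma")
        for f in ("sigma_v", "sigma_i"):
            v = getattr(self, f)
            if not (0.0 <= v <= 1.0):
                out.append(f"{self.name}: {f} outside [0, 1]")
        return out


@dataclass
class SpeciesPhysiology:
    """Whole-body anatomical/physiological parameter set for one species."""

    species: str
    body_weight: float          # kg
    hematocrit: float           # fraction
    FcRn_total: float           # endosomal FcRn concentration, nM
    V_blood_plasma: float       # central (arterial+venous) plasma pool, L
    V_blood_cell: float         # central blood-cell pool, L
    V_lymphnode: float          # single well-mixed lymph-node pool, L
    tissues: list[TissueSpec] = field(default_factory=list)

    def tissue(self, name: str) -> TissueSpec:
        for t in self.tissues:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def tissue_names(self) -> list[str]:
        return [t.name for t in self.tissues]


_FIELD_COLUMNS = ("V_plasma", "V_bloodcell", "V_endosomal", "V_interstitial",
                  "V_cellular", "Q_plasma", "L_lymph", "sigma_v", "sigma_i")

_META_FIELDS = ("body_weight", "hematocrit", "FcRn_total", "V_blood_plasma",
                "V_blood_cell", "V_lymphnode")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("adcpbpk").joinpath("data", name)))


def load_species_physiology(species: str, source: str | Path | None = None) -> SpeciesPhysiology:
    """Load and validate the physiology table for one species.

    Parameters
    ----------
    species : one of ``mouse``, ``rat``, ``monkey``, ``human``
    source : optional path to a physiology file; defaults to the packaged
        per-species table.

    Raises
    ------
    UnsupportedSpeciesError
        for species outside the four-species set (when using packaged data).
    PhysiologySchemaError
        when the file is missing fields or cannot be parsed; the message
        names the offending field or row.
    """
    if source is None:
        if species not in SPECIES:
            raise UnsupportedSpeciesError(
                f"species {species!r} not supported; expected one of {SPECIES}")
        source = _data_path(f"physiology_{species}.csv")
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)

    meta: dict[str, float] = {}
    tissues: list[TissueSpec] = []
    header: list[str] | None = None
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#!"):
            try:
                key, val = line[2:].split("=", 1)
            except ValueError as e:
                raise PhysiologySchemaError(f"malformed metadata line: {line!r}") from e
            meta[key.strip()] = val.strip()
            continue
        if line.startswith("#"):
            continue
        cells = [c.strip() for c in line.split(",")]
        if header is None:
            header = cells
            missing = [c for c in ("tissue",) + _FIELD_COLUMNS if c not in header]
            if missing:
                raise PhysiologySchemaError(f"missing column(s): {', '.join(missing)}")
            continue
        row = dict(zip(header, cells))
        try:
            tissues.append(TissueSpec(
                name=row["tissue"],
                **{f: float(row[f]) for f in _FIELD_COLUMNS}))
        except (KeyError, ValueError) as e:
            raise PhysiologySchemaError(
                f"bad value in row for tissue {row.get('tissue', '?')!r}: {e}") from e

    for f in _META_FIELDS:
        if f not in meta:
            raise PhysiologySchemaError(f"missing metadata field {f!r}")
    try:
        metavals = {f: float(meta[f]) for f in _META_FIELDS}
    except ValueError as e:
        raise PhysiologySchemaError(f"non-numeric metadata field: {e}") from e

    phys = SpeciesPhysiology(species=meta.get("species", species), tissues=tissues, **metavals)
    return phys


def write_species_physiology(phys: SpeciesPhysiology, path: str | Path,
                             provenance: str | None = None) -> None:
    """Write a physiology table; ``load_species_physiology`` round-trips it bit-exactly."""
    lines = []
    if provenance:
        for ln in provenance.splitlines():
            lines.append(f"# {ln}")
    lines.append("# volumes in L, flows in L/h, reflection coefficients dimensionless")
    lines.append(f"#!species = {phys.species}")
    for f in _META_FIELDS:
        lines.append(f"#!{f} = {getattr(phys, f)!r}")
    lines.append("tissue," + ",".join(_FIELD_COLUMNS))
    for t in phys.tissues:
        lines.append(t.name + "," + ",".join(repr(getattr(t, f)) for f in _FIELD_COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n")


def validate_physiology(phys: SpeciesPhysiology, flow_tolerance: float = 0.01) -> list[str]:
    """Return the list of violated invariants (empty when the physiology is valid).

    Checks per-tissue volume/flow/reflection constraints, the canonical tissue
    set, and the flow balance: summed non-lung organ plasma flows must agree
    with the lung (total) plasma flow within ``flow_tolerance``.
    """
    report: list[str] = []
    for t in phys.tissues:
        report.extend(t.violations())
    names = phys.tissue_names
    if sorted(names) != sorted(TISSUE_ORDER):
        missing = set(TISSUE_ORDER) - set(names)
        extra = set(names) - set(TISSUE_ORDER)
        if missing:
            report.append(f"missing tissue(s): {', '.join(sorted(missing))}")
        if extra:
            report.append(f"unexpected tissue(s): {', '.join(sorted(extra))}")
    if phys.body_weight <= 0:
        report.append("body_weight must be positive")
    if not (0 < phys.hematocrit < 1):
        report.append("hematocrit outside (0, 1)")
    for f in ("FcRn_total", "V_blood_plasma", "V_blood_cell", "V_lymphnode"):
        if getattr(phys, f) < 0:
            report.append(f"{f} is negative")
    try:
        q_lung = phys.tissue("lung").Q_plasma
        q_sum = sum(t.Q_plasma for t in phys.tissues if t.name != "lung")
        if q_lung > 0 and not math.isclose(q_sum, q_lung, rel_tol=flow_tolerance):
            report.append(
                f"flow imbalance: sum of organ plasma flows {q_sum:.4g} L/h vs "
                f"lung flow {q_lung:.4g} L/h")
    except KeyError:
        pass
    return report


def physiology_to_dict(phys: SpeciesPhysiology) -> dict:
    """Plain-dict form (for hashing/metadata in result files)."""
    return asdict(phys)
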