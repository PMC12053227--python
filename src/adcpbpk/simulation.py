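"""Coupled ADC simulation: dose regimens, stiff integration, mass-balance audit.

The full state couples, per dose cohort, the antibody PBPK block and a global
average-DAR ODE, with a shared payload PBPK block receiving deconjugation and
degradation release fluxes, cumulative ledgers for every release and
elimination pathway, and (optionally) the cell-level tumor model.

Multi-dose DAR handling: the model tracks conjugated-payload amount and
antibody amount implicitly — DAR is integrated as dDAR/dt = -k_dec(DAR)*DAR
and reset amount-weighted at each bolus,
DAR <- (DAR*A_mab + DAR0*dose)/(A_mab + dose).  In ``per_cohort`` mode each
administration instead carries its own antibody block and DAR state, which
makes the system exactly linear per cohort (used for superposition checks).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import antibody, payload as payload_mod
from .coupling import analyte_assembly
from .parameters import AdcParameterSet, default_parameters, kdeg_for_species
from .physiology import SpeciesPhysiology, TISSUE_ORDER, load_species_physiology
from .topology import PhysArrays
from .tumor import TumorParams
from .units import HOURS_PER_DAY, dose_mgkg_to_nmol


class IntegrationError(RuntimeError):
    """Raised when the stiff solver fails; carries the solver diagnostic."""


@dataclass
class DoseRegimen:
    """IV bolus dosing schedule (times in days, dose in mg/kg)."""

    dose_per_admin: float
    times_days: tuple[float, ...]
    route: str = "iv_bolus"

    def __post_init__(self):
        if self.dose_per_admin < 0:
            raise ValueError("dose must be >= 0")
        t = tuple(float(x) for x in self.times_days)
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("dose times must be strictly increasing")
        self.times_days = t


REGIMEN_LABELS = ("single", "Q3W", "weekly3_of_28")


def build_regimen(label: str, dose: float, n_cycles: int = 1) -> DoseRegimen:
    """Construct a named clinical regimen.

    ``single``: one dose at t=0.  ``Q3W``: every 21 days.  ``weekly3_of_28``:
    doses on days 0, 7, 14 of each 28-day cycle.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if label == "single":
        times = (0.0,)
    elif label == "Q3W":
        times = tuple(21.0 * c for c in range(n_cycles))
    elif label == "weekly3_of_28":
        times = tuple(28.0 * c + d for c in range(n_cycles) for d in (0.0, 7.0, 14.0))
    else:
        raise ValueError(f"unknown regimen label {label!r}; expected one of {REGIMEN_LABELS}")
    return DoseRegimen(dose_per_admin=dose, times_days=times)


class _Index:
    """State-vector layout for a given cohort count / tumor configuration."""

    def __init__(self, n_tissues: int, n_cohorts: int, has_tumor: bool):
        self.n = n_tissues
        self.n_cohorts = n_cohorts
        self.has_tumor = has_tumor
        n = n_tissues
        self.block = 4 * n + 2 + (3 if has_tumor else 0) + 1  # per-cohort mAb block
        off = 0
        self.cohort_offsets = []
        for _ in range(n_cohorts):
            self.cohort_offsets.append(off)
            off += self.block
        # shared payload block
        self.p_ec = slice(off, off + n); off += n
        self.p_bc = slice(off, off + n); off += n
        self.p_cell = slice(off, off + n); off += n
        self.p_bp = off; off += 1
        self.p_bbc = off; off += 1
        if has_tumor:
            self.t_mex = off; off += 1
            self.t_min = off; off += 1
        # ledgers (nmol)
        self.l_deg_mab = off; off += 1
        self.l_plasma_deconj = off; off += 1
        self.l_deconj_tissue = slice(off, off + n); off += n
        self.l_deg_tissue = slice(off, off + n); off += n
        self.l_tumor = off; off += 1
        self.l_hepatic = off; off += 1
        self.n_states = off

    def mab(self, c: int):
        """Slices of cohort c's antibody block: (Cv, Ceu, Ceb, Ci, Cb, Cln, tumor, dar)."""
        o = self.cohort_offsets[c]
        n = self.n
        sl = dict(
            Cv=slice(o, o + n), Ceu=slice(o + n, o + 2 * n),
            Ceb=slice(o + 2 * n, o + 3 * n), Ci=slice(o + 3 * n, o + 4 * n),
            Cb=o + 4 * n, Cln=o + 4 * n + 1)
        pos = o + 4 * n + 2
        if self.has_tumor:
            sl["T_free"], sl["T_bound"], sl["T_int"] = pos, pos + 1, pos + 2
            pos += 3
        sl["dar"] = pos
        return sl


class AdcPbpkModel:
    """Whole-body PBPK model for an MMAE-based ADC in one species.

    Built from a species physiology and an ADC parameter set (packaged
    defaults when only the species name is given); ``simulate`` integrates the
    coupled system for a dose regimen and returns a :class:`SimulationResult`.
    """

    def __init__(self, species: str | None = None,
                 params: AdcParameterSet | None = None,
                 phys: SpeciesPhysiology | None = None,
                 tumor: TumorParams | None = None):
        if phys is None:
            if species is None:
                raise ValueError("give either a species name or a SpeciesPhysiology")
            phys = load_species_physiology(species)
        if params is None:
            params = default_parameters(species or phys.species)
        params.validate()
        if tumor is not None:
            tumor.validate()
        self.phys = phys
        self.params = params
        self.tumor = tumor
        self.arr = PhysArrays(phys)
        self._pl = self.arr.payload_arrays(params)
        self.cl_hep = payload_mod.hepatic_clearance_rate(
            params.payload.CLint, params.payload.fup, phys.body_weight)
        self.kdeg_eff = kdeg_for_species(params.mab.kdeg_base, params.coupling.f_Kdeg)

    # ------------------------------------------------------------------ RHS
    def _rhs(self, t, y, idx: _Index, mask=(1.0, 1.0, 1.0)):
        arr = self.arr
        p = self.params
        dp = p.deconjugation
        dy = np.zeros_like(y)
        n = arr.n

        src_ec = np.zeros(n)
        src_cell = np.zeros(n)
        src_bp = 0.0
        d_deconj_tissue = np.zeros(n)
        d_deg_tissue = np.zeros(n)
        d_plasma = 0.0
        d_deg_mab = 0.0
        d_tumor = 0.0
        d_mex_src = 0.0
        d_min_src = 0.0

        for c in range(idx.n_cohorts):
            sl = idx.mab(c)
            Cv, Ceu, Ceb, Ci = y[sl["Cv"]], y[sl["Ceu"]], y[sl["Ceb"]], y[sl["Ci"]]
            Cb, Cln = y[sl["Cb"]], y[sl["Cln"]]
            dar = max(y[sl["dar"]], 0.0)
            # stable form of the empirical DAR-dependent rate, per hour
            kdec_h = (dp.alpha - (dp.alpha - dp.beta) / (dp.F * dar ** dp.tau + 1.0)) \
                * dp.SF / HOURS_PER_DAY

            (dCv, dCeu, dCeb, dCi, dCb, dCln, deg_flux) = antibody.mab_rhs(
                arr, p.mab, Cv, Ceu, Ceb, Ci, Cb, Cln, kdeg=self.kdeg_eff)

            if idx.has_tumor:
                tu = self.tumor
                Tf, Tb, Ti = y[sl["T_free"]], y[sl["T_bound"]], y[sl["T_int"]]
                ag_free = max(tu.antigen_total - Tb, 0.0)
                f_vasc = tu.k_vasc_mab * tu.V_ex * (Cb - Tf)       # nmol/h
                bind = tu.kon_Ag * Tf * ag_free - tu.koff_Ag * Tb  # nM/h in V_ex
                internal = tu.k_int * Tb                           # nM/h in V_ex
                deg_t = tu.k_deg_tumor * Ti * tu.V_cell            # nmol/h
                dy[sl["T_free"]] = f_vasc / tu.V_ex - bind
                dy[sl["T_bound"]] = bind - internal
                dy[sl["T_int"]] = internal * tu.V_ex / tu.V_cell - tu.k_deg_tumor * Ti
                dCb -= f_vasc / arr.Vb
                d_deg_mab += deg_t
                # tumor release fluxes: deconjugation of every tumor ADC pool
                # plus DAR-equivalent release on intracellular degradation
                rel_ex = kdec_h * dar * (Tf + Tb) * tu.V_ex
                rel_in = kdec_h * dar * Ti * tu.V_cell + deg_t * dar
                d_mex_src += rel_ex
                d_min_src += rel_in
                d_tumor += rel_ex + rel_in

            dy[sl["Cv"]], dy[sl["Ceu"]], dy[sl["Ceb"]], dy[sl["Ci"]] = dCv, dCeu, dCeb, dCi
            dy[sl["Cb"]], dy[sl["Cln"]] = dCb, dCln
            dy[sl["dar"]] = -kdec_h * dar

            # deconjugation release: every antibody-containing pool of each tissue
            src_ec += kdec_h * dar * (Cv * arr.Vp + Ci * arr.Vi + (Ceu + Ceb) * arr.Ve)
            src_bp += kdec_h * dar * (Cb * arr.Vb + Cln * arr.Vln)
            src_cell += deg_flux * dar
            d_deconj_tissue += kdec_h * dar * (Cv * arr.Vp + Ci * arr.Vi
                                               + (Ceu + Ceb) * arr.Ve)
            d_plasma += kdec_h * dar * (Cb * arr.Vb + Cln * arr.Vln)
            d_deg_tissue += deg_flux * dar
            d_deg_mab += deg_flux.sum()

        kp, ps_cell, ps_bc, ps_bc_blood = self._pl
        Cec, Cbc, Cc = y[idx.p_ec], y[idx.p_bc], y[idx.p_cell]
        Cbp, Cbbc = y[idx.p_bp], y[idx.p_bbc]
        m_plasma, m_tissue, m_tumor = mask
        (dCec, dCbc, dCc, dCbp, dCbbc, elim) = payload_mod.mmae_rhs(
            arr, kp, ps_cell, ps_bc, ps_bc_blood, p.payload.Kp_BC, self.cl_hep,
            Cec, Cbc, Cc, Cbp, Cbbc, src_ec=src_ec * m_tissue,
            src_cell=src_cell * m_tissue, src_bp=src_bp * m_plasma)

        if idx.has_tumor:
            tu = self.tumor
            Mex, Min = y[idx.t_mex], y[idx.t_min]
            f_vasc_m = tu.k_vasc_mmae * tu.V_ex * (Cbp - Mex)          # nmol/h
            ex_cell = tu.ps_payload * tu.V_cell * (Mex - Min / tu.Kp_tumor)
            dy[idx.t_mex] = (f_vasc_m - ex_cell + d_mex_src * m_tumor) / tu.V_ex
            dy[idx.t_min] = (ex_cell + d_min_src * m_tumor) / tu.V_cell
            dCbp -= f_vasc_m / arr.Vb

        dy[idx.p_ec], dy[idx.p_bc], dy[idx.p_cell] = dCec, dCbc, dCc
        dy[idx.p_bp], dy[idx.p_bbc] = dCbp, dCbbc

        dy[idx.l_deg_mab] = d_deg_mab
        dy[idx.l_plasma_deconj] = d_plasma
        dy[idx.l_deconj_tissue] = d_deconj_tissue
        dy[idx.l_deg_tissue] = d_deg_tissue
        dy[idx.l_tumor] = d_tumor
        dy[idx.l_hepatic] = elim
        return dy

    def _cohort_amount(self, y, idx: _Index, c: int) -> float:
        sl = idx.mab(c)
        amt = antibody.total_mab_amount(
            self.arr, y[sl["Cv"]], y[sl["Ceu"]], y[sl["Ceb"]], y[sl["Ci"]],
            y[sl["Cb"]], y[sl["Cln"]])
        if idx.has_tumor:
            amt += (y[sl["T_free"]] + y[sl["T_bound"]]) * self.tumor.V_ex \
                + y[sl["T_int"]] * self.tumor.V_cell
        return amt

    # ------------------------------------------------------------- simulate
    def simulate(self, regimen: DoseRegimen, t_end: float,
                 rtol: float = 1e-8, atol: float = 1e-12, n_points: int = 400,
                 dar_mode: str = "pooled", method: str = "BDF",
                 source_mask: dict | None = None) -> "SimulationResult":
        """Integrate the coupled system.

        Parameters
        ----------
        regimen : dosing schedule (times in days)
        t_end : simulation horizon in days; must not precede the last dose
        rtol, atol : solver tolerances (atol in nM)
        n_points : size of the output time grid
        dar_mode : ``pooled`` (amount-weighted global DAR, default) or
            ``per_cohort`` (one antibody block and DAR state per administration)
        source_mask : optional dict with boolean entries ``plasma``, ``tissues``,
            ``tumor`` selecting which release pathways feed the payload system.
            The payload subsystem is linear in its sources, so masked runs sum
            to the full run; used for source attribution.  Ledgers still record
            the true releases, so the payload conservation audit does not apply
            to masked runs.

        The solver is restarted at every bolus.  Deterministic given inputs
        and tolerances.
        """
        if dar_mode not in ("pooled", "per_cohort"):
            raise ValueError("dar_mode must be 'pooled' or 'per_cohort'")
        times = regimen.times_days
        if times and t_end < times[-1]:
            raise ValueError("t_end precedes the last dose time")
        if dar_mode == "per_cohort" and self.tumor is not None:
            raise ValueError("per-cohort mode does not support the tumor model "
                             "(cohorts would compete for antigen)")

        mask = (1.0, 1.0, 1.0)
        if source_mask is not None:
            unknown = set(source_mask) - {"plasma", "tissues", "tumor"}
            if unknown:
                raise KeyError(f"unknown source(s) in mask: {sorted(unknown)}")
            mask = tuple(float(bool(source_mask.get(k, True)))
                         for k in ("plasma", "tissues", "tumor"))

        n_cohorts = max(1, len(times)) if dar_mode == "per_cohort" else 1
        idx = _Index(self.arr.n, n_cohorts, self.tumor is not None)
        dar0 = self.params.coupling.DAR0
        dose_nmol = dose_mgkg_to_nmol(regimen.dose_per_admin, self.phys.body_weight,
                                      self.params.coupling.MW_mAb)

        y = np.zeros(idx.n_states)
        for c in range(n_cohorts):
            y[idx.mab(c)["dar"]] = dar0

        t_end_h = t_end * HOURS_PER_DAY
        grid = np.linspace(0.0, t_end_h, n_points)
        edges = sorted({0.0, t_end_h, *(t * HOURS_PER_DAY for t in times)})
        dose_at = {round(t * HOURS_PER_DAY, 9): i for i, t in enumerate(times)}

        ts, ys = [], []
        for k, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
            if round(a, 9) in dose_at and dose_nmol > 0:
                y = self._apply_bolus(y, idx, dose_at[round(a, 9)], dose_nmol,
                                      dar0, dar_mode)
            t_eval = np.concatenate(([a], grid[(grid > a) & (grid < b)], [b]))
            sol = solve_ivp(self._rhs, (a, b), y, args=(idx, mask), method=method,
                            rtol=rtol, atol=atol, t_eval=t_eval)
            if not sol.success and method != "LSODA":
                # BDF occasionally stalls on the restart step after a bolus when
                # cohort blocks hold states of wildly different magnitudes
                sol = solve_ivp(self._rhs, (a, b), y, args=(idx, mask), method="LSODA",
                                rtol=rtol, atol=atol, t_eval=t_eval)
            if not sol.success:
                raise IntegrationError(f"solver failed on [{a:.3g}, {b:.3g}] h: {sol.message}")
            ts.append(sol.t)
            ys.append(sol.y)
            y = sol.y[:, -1].copy()
        if round(edges[-1], 9) in dose_at and dose_nmol > 0:
            # regimen ends exactly at a dose time (t_end == last dose)
            y = self._apply_bolus(y, idx, dose_at[round(edges[-1], 9)], dose_nmol,
                                  dar0, dar_mode)
            ts.append(np.array([edges[-1]]))
            ys.append(y[:, None])

        t_all = np.concatenate(ts)
        y_all = np.concatenate(ys, axis=1)
        meta = {
            "species": self.phys.species,
            "solver": {"method": method, "rtol": rtol, "atol": atol},
            "dar_mode": dar_mode,
            "params_hash": hashlib.sha256(
                json.dumps(self.params.to_dict(), sort_keys=True, default=str)
                .encode()).hexdigest()[:16],
        }
        return SimulationResult(
            t_days=t_all / HOURS_PER_DAY, Y=y_all, idx=idx, model=self,
            regimen=regimen, dose_nmol_per_admin=dose_nmol, metadata=meta)

    def _apply_bolus(self, y, idx: _Index, dose_index: int, dose_nmol: float,
                     dar0: float, dar_mode: str):
        y = y.copy()
        c = dose_index if dar_mode == "per_cohort" else 0
        sl = idx.mab(c)
        if dar_mode == "pooled":
            a_mab = self._cohort_amount(y, idx, 0)
            y[sl["dar"]] = (y[sl["dar"]] * a_mab + dar0 * dose_nmol) / (a_mab + dose_nmol)
        else:
            y[sl["dar"]] = dar0
        y[sl["Cb"]] += dose_nmol / self.arr.Vb
        return y


@dataclass
class SimulationResult:
    """Molar state trajectories plus derived analyte profiles and ledgers."""

    t_days: np.ndarray
    Y: np.ndarray
    idx: _Index
    model: AdcPbpkModel
    regimen: DoseRegimen
    dose_nmol_per_admin: float
    metadata: dict = field(default_factory=dict)

    # ------------------------------------------------------------ raw access
    @property
    def tumor(self):
        return self.model.tumor

    def _sum_cohorts(self, key: str) -> np.ndarray:
        out = 0.0
        for c in range(self.idx.n_cohorts):
            out = out + self.Y[self.idx.mab(c)[key]]
        return np.asarray(out)

    def mab_tissue(self, sub: str) -> np.ndarray:
        """Per-tissue antibody concentration (nM), summed over cohorts.

        ``sub`` is one of ``vascular``, ``endosomal_unbound``, ``endosomal_bound``,
        ``interstitial``.
        """
        key = {"vascular": "Cv", "endosomal_unbound": "Ceu",
               "endosomal_bound": "Ceb", "interstitial": "Ci"}[sub]
        return self._sum_cohorts(key)

    def payload_tissue(self, sub: str) -> np.ndarray:
        sl = {"extracellular": self.idx.p_ec, "bloodcell": self.idx.p_bc,
              "cellular": self.idx.p_cell}[sub]
        return self.Y[sl]

    def tumor_state(self, name: str) -> np.ndarray:
        if self.tumor is None:
            raise ValueError("simulation was run without a tumor")
        if name in ("adc_free", "adc_bound", "adc_internalized"):
            key = {"adc_free": "T_free", "adc_bound": "T_bound",
                   "adc_internalized": "T_int"}[name]
            return self._sum_cohorts(key)
        sl = {"mmae_extracellular": self.idx.t_mex,
              "mmae_intracellular": self.idx.t_min}[name]
        return self.Y[sl]

    def mab_plasma_nM(self) -> np.ndarray:
        return self._sum_cohorts("Cb")

    def mmae_plasma_nM(self) -> np.ndarray:
        return self.Y[self.idx.p_bp]

    def dar(self) -> np.ndarray:
        """Average DAR over time (amount-weighted across cohorts)."""
        if self.idx.n_cohorts == 1:
            return self.Y[self.idx.mab(0)["dar"]]
        num = np.zeros(self.Y.shape[1])
        den = np.zeros(self.Y.shape[1])
        for c in range(self.idx.n_cohorts):
            a = self._amount_series(c)
            num += self.Y[self.idx.mab(c)["dar"]] * a
            den += a
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)

    def _amount_series(self, c: int) -> np.ndarray:
        arr = self.model.arr
        sl = self.idx.mab(c)
        amt = (self.Y[sl["Cv"]].T @ arr.Vp + (self.Y[sl["Ceu"]] + self.Y[sl["Ceb"]]).T @ arr.Ve
               + self.Y[sl["Ci"]].T @ arr.Vi)
        amt = amt + self.Y[sl["Cb"]] * arr.Vb + self.Y[sl["Cln"]] * arr.Vln
        if self.idx.has_tumor:
            tu = self.tumor
            amt = amt + (self.Y[sl["T_free"]] + self.Y[sl["T_bound"]]) * tu.V_ex \
                + self.Y[sl["T_int"]] * tu.V_cell
        return amt

    def total_mab_nmol(self) -> np.ndarray:
        return sum(self._amount_series(c) for c in range(self.idx.n_cohorts))

    def conjugated_payload_nmol(self) -> np.ndarray:
        return sum(self._amount_series(c) * self.Y[self.idx.mab(c)["dar"]]
                   for c in range(self.idx.n_cohorts))

    def total_free_payload_nmol(self) -> np.ndarray:
        arr = self.model.arr
        amt = (self.Y[self.idx.p_ec].T @ arr.Vec + self.Y[self.idx.p_bc].T @ arr.Vbc
               + self.Y[self.idx.p_cell].T @ arr.Vc)
        amt = amt + self.Y[self.idx.p_bp] * arr.Vb + self.Y[self.idx.p_bbc] * arr.Vb_bc
        if self.idx.has_tumor:
            tu = self.tumor
            amt = amt + self.Y[self.idx.t_mex] * tu.V_ex + self.Y[self.idx.t_min] * tu.V_cell
        return amt

    def ledgers(self) -> dict[str, np.ndarray]:
        """Cumulative molar ledgers (nmol): releases, degradation, elimination."""
        return {
            "degraded_mab": self.Y[self.idx.l_deg_mab],
            "plasma_deconjugation": self.Y[self.idx.l_plasma_deconj],
            "tissue_deconjugation": self.Y[self.idx.l_deconj_tissue],
            "tissue_degradation": self.Y[self.idx.l_deg_tissue],
            "tumor_release": self.Y[self.idx.l_tumor],
            "hepatic_elimination": self.Y[self.idx.l_hepatic],
        }

    # ------------------------------------------------------------- derived
    def plasma_analytes(self) -> pd.DataFrame:
        """Plasma analyte profiles in reporting units (µg/mL, ng/mL)."""
        cp = self.model.params.coupling
        a = analyte_assembly(self.mab_plasma_nM(), self.dar(), self.mmae_plasma_nM(),
                             cp.MW_mAb, cp.MW_MMAE)
        return pd.DataFrame({"time_day": self.t_days, **a, "DAR": self.dar()})

    def auc_plasma(self, analyte: str) -> float:
        """Trapezoidal plasma AUC over the simulated horizon (reporting units·day)."""
        df = self.plasma_analytes()
        return float(np.trapezoid(df[analyte].to_numpy(), df["time_day"].to_numpy()))

    def mass_balance(self) -> dict[str, float]:
        """Relative errors of the antibody- and payload-mole conservation identities."""
        dosed = self.dose_nmol_per_admin * len(self.regimen.times_days)
        led = self.ledgers()
        mab_final = self.total_mab_nmol()[-1] + led["degraded_mab"][-1]
        conj = self.conjugated_payload_nmol()[-1]
        free = self.total_free_payload_nmol()[-1]
        pay_final = conj + free + led["hepatic_elimination"][-1]
        released = (led["plasma_deconjugation"][-1] + led["tissue_deconjugation"][:, -1].sum()
                    + led["tissue_degradation"][:, -1].sum() + led["tumor_release"][-1])
        if dosed == 0:
            return {"mab_rel_error": 0.0, "payload_rel_error": 0.0,
                    "ledger_rel_error": 0.0}
        dar0 = self.model.params.coupling.DAR0
        return {
            "mab_rel_error": abs(mab_final - dosed) / dosed,
            "payload_rel_error": abs(pay_final - dar0 * dosed) / (dar0 * dosed),
            "ledger_rel_error": abs(free + led["hepatic_elimination"][-1] - released)
            / max(released, 1e-300),
        }

    def to_frame(self) -> pd.DataFrame:
        """Long-format trajectory table (time, tissue, sub-compartment, analyte, value, unit)."""
        cp = self.model.params.coupling
        rows = []
        dar = self.dar()
        for j, name in enumerate(TISSUE_ORDER):
            for sub, key in (("vascular", "vascular"), ("interstitial", "interstitial")):
                mab = self.mab_tissue(key)[j]
                rows.append(pd.DataFrame({
                    "time_day": self.t_days, "tissue": name, "sub_compartment": sub,
                    "analyte": "total_mAb", "value": mab * cp.MW_mAb * 1e-6,
                    "unit": "ug/mL"}))
            for sub in ("extracellular", "cellular"):
                mm = self.payload_tissue(sub)[j]
                rows.append(pd.DataFrame({
                    "time_day": self.t_days, "tissue": name, "sub_compartment": sub,
                    "analyte": "unconjugated_MMAE", "value": mm * cp.MW_MMAE * 1e-3,
                    "unit": "ng/mL"}))
        pl = self.plasma_analytes()
        for analyte, unit in (("total_mAb_ugml", "ug/mL"),
                              ("conjugated_MMAE_ngml", "ng/mL"),
                              ("unconjugated_MMAE_ngml", "ng/mL")):
            rows.append(pd.DataFrame({
                "time_day": self.t_days, "tissue": "blood", "sub_compartment": "plasma",
                "analyte": analyte.rsplit("_", 1)[0], "value": pl[analyte],
                "unit": unit}))
        rows.append(pd.DataFrame({
            "time_day": self.t_days, "tissue": "blood", "sub_compartment": "plasma",
            "analyte": "DAR", "value": dar, "unit": ""}))
        return pd.concat(rows, ignore_index=True)

    def plot_plasma(self, ax=None, logy: bool = True):
        """Plot the three plasma analyte profiles (and DAR on a twin axis)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4.5))
        pl = self.plasma_analytes()
        ax.plot(pl["time_day"], pl["total_mAb_ugml"], label="total mAb (µg/mL)")
        ax.plot(pl["time_day"], pl["conjugated_MMAE_ngml"], label="conjugated MMAE (ng/mL)")
        ax.plot(pl["time_day"], pl["unconjugated_MMAE_ngml"], label="unconjugated MMAE (ng/mL)")
        if logy:
            ax.set_yscale("log")
        ax.set_xlabel("time (days)")
        ax.set_ylabel("plasma concentration")
        ax2 = ax.twinx()
        ax2.plot(pl["time_day"], pl["DAR"], color="0.4", ls="--", label="DAR")
        ax2.set_ylabel("average DAR")
        ax2.set_ylim(0, self.model.params.coupling.DAR0 * 1.05)
        ax.legend(loc="upper right", fontsize=8)
        return ax

    def summary(self) -> str:
        """Human-readable run summary."""
        mb = self.mass_balance()
        pl = self.plasma_analytes()
        lines = [
            f"ADC PBPK simulation — {self.metadata.get('species', '?')}",
            f"  regimen: {self.regimen.dose_per_admin} mg/kg at days "
            f"{list(self.regimen.times_days)}",
            f"  horizon: {self.t_days[-1]:.1f} d, {self.Y.shape[0]} states, "
            f"dar_mode={self.metadata.get('dar_mode')}",
            f"  plasma AUC total mAb:          {np.trapezoid(pl['total_mAb_ugml'], pl['time_day']):.4g} ug/mL*day",
            f"  plasma AUC conjugated MMAE:    {np.trapezoid(pl['conjugated_MMAE_ngml'], pl['time_day']):.4g} ng/mL*day",
            f"  plasma AUC unconjugated MMAE:  {np.trapezoid(pl['unconjugated_MMAE_ngml'], pl['time_day']):.4g} ng/mL*day",
            f"  final DAR: {self.dar()[-1]:.3f} (DAR0 {self.model.params.coupling.DAR0})",
            f"  mass balance: mAb {mb['mab_rel_error']:.2e}, payload {mb['payload_rel_error']:.2e}",
        ]
        return "\n".join(lines)


def simulate(species: str, regimen: DoseRegimen, params: AdcParameterSet | None = None,
             t_end: float = 42.0, tumor: TumorParams | None = None,
             **solver_options) -> SimulationResult:
    """Convenience wrapper: build the model and run one simulation."""
    model = AdcPbpkModel(species=species, params=params, tumor=tumor)
    return model.simulate(regimen, t_end, **solver_options)


def mass_balance_audit(result: SimulationResult) -> dict[str, float]:
    """Conservation audit of a finished run (relative errors at final time)."""
    return result.mass_balance()
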