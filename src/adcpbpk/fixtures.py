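"""Seeded generator of synthetic multi-study observed PK datasets.

Emulates the structure of pooled literature data: several studies per
species, each with its own dose level and sparse sampling schedule, reporting
plasma concentrations of the ADC analytes with multiplicative lognormal
noise.  The noise is unit-mean (``exp(N(-sigma^2/2, sigma^2))``) so pooled
means are unbiased for the true profile.  Deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import AdcParameterSet, default_parameters
from .simulation import AdcPbpkModel, DoseRegimen

#: default sparse sampling schedule (days), typical of multi-study rat data
DEFAULT_TIMES = (0.1, 0.25, 1.0, 3.0, 7.0, 14.0, 21.0, 28.0, 42.0)

_ANALYTE_COLUMNS = {
    "total_mAb": ("total_mAb_ugml", "ug/mL"),
    "conjugated_MMAE": ("conjugated_MMAE_ngml", "ng/mL"),
    "unconjugated_MMAE": ("unconjugated_MMAE_ngml", "ng/mL"),
}


@dataclass
class FixtureSpec:
    """Conditions for one synthetic multi-study dataset."""

    species: str = "rat"
    params: AdcParameterSet | None = None
    dose_levels: tuple[float, ...] = (5.0, 10.0, 20.0)   # mg/kg, cycled per study
    times_day: tuple[float, ...] = DEFAULT_TIMES
    n_studies: int = 6
    cv: float = 0.30            # multiplicative lognormal CV
    seed: int = 0
    analytes: tuple[str, ...] = ("total_mAb", "conjugated_MMAE", "unconjugated_MMAE")

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("CV must be >= 0")
        if self.n_studies < 1:
            raise ValueError("need at least one study")


def true_profiles(spec: FixtureSpec, reference_dose: float = 1.0,
                  **solver_options) -> pd.DataFrame:
    """Noise-free plasma analyte profiles at the reference dose (mg/kg).

    The model is linear in dose, so study-level truths are obtained by
    scaling these profiles.
    """
    params = spec.params or default_parameters(spec.species)
    model = AdcPbpkModel(species=spec.species, params=params)
    regimen = DoseRegimen(dose_per_admin=reference_dose, times_days=(0.0,))
    res = model.simulate(regimen, t_end=max(spec.times_day) * 1.05, **solver_options)
    return res.plasma_analytes()


def generate_fixture(spec: FixtureSpec, truth: pd.DataFrame | None = None,
                     **solver_options) -> pd.DataFrame:
    """Synthetic observed dataset in the canonical observed-record schema.

    ``truth`` may carry precomputed reference-dose profiles (the output of
    :func:`true_profiles`) to avoid re-simulating when generating many
    replicate datasets.
    """
    rng = np.random.default_rng(spec.seed)
    if truth is None:
        truth = true_profiles(spec, **solver_options)
    t_truth = truth["time_day"].to_numpy()
    sigma = np.sqrt(np.log1p(spec.cv ** 2))

    rows = []
    for s in range(spec.n_studies):
        dose = spec.dose_levels[s % len(spec.dose_levels)]
        for analyte in spec.analytes:
            col, unit = _ANALYTE_COLUMNS[analyte]
            base = np.interp(spec.times_day, t_truth, truth[col].to_numpy()) * dose
            noise = np.exp(rng.normal(-sigma ** 2 / 2.0, sigma, size=len(base))) \
                if sigma > 0 else np.ones(len(base))
            for t, c in zip(spec.times_day, base * noise):
                rows.append({"study": f"study{s + 1:02d}", "species": spec.species,
                             "analyte": analyte, "matrix": "plasma",
                             "dose_mgkg": dose, "time_day": t, "conc": c,
                             "unit": unit})
    return pd.DataFrame(rows)
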