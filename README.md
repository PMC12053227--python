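# adcpbpk

Translational whole-body physiologically-based pharmacokinetic (PBPK)
simulator for MMAE-based antibody-drug conjugates (ADCs), for modelers who
need tissue-level exposure of the four ADC analytes (total antibody,
conjugated/unconjugated MMAE, and the drug-to-antibody ratio, DAR) in mouse,
rat, monkey and human — the quantities that drive exposure–toxicity and
exposure–efficacy analysis but cannot be measured clinically.

## The model

Two coupled whole-body PBPK models — a platform antibody model (convection,
lymph, pinocytosis, kinetic FcRn binding with recycling/transcytosis,
lysosomal degradation) and a small-molecule model for free MMAE
(permeability-limited blood-cell and cellular partitioning, hepatic
clearance of unbound drug) — are linked by two payload-release processes:

* **DAR-dependent deconjugation** with the empirical rate
  `k_dec = (α − (α−β)·DAR^(−τ)/(F + DAR^(−τ)))·SF` and `dDAR/dt = −k_dec·DAR`
  (α = 0.0806 d⁻¹, β = 0.0102 d⁻¹, F = 0.282, τ = 5.68), reproducing the
  biphasic DAR decline; the species scaling factor follows allometry,
  `SF = (BW/BW_mouse)^(−0.25)` → 1, 0.6, 0.3, 0.1 for mouse, rat, monkey,
  human;
* **degradation-driven release**: each ADC degraded in an endosome releases
  DAR payload molecules; ADC degradation is `f_Kdeg`-fold faster than the
  naked antibody (1, 1, 3, 4 by species — conjugation-enhanced clearance).

A cell-level tumor module (antigen binding, internalization, intracellular
release; IHC-graded antigen levels) and the evaluation toolbox (dose
normalization, pooled observed DAR profiles, sparse-sampling Bailer AUC,
percent prediction error, SF fitting, Kp sensitivity, payload source
attribution) round out the package. See `docs/methods.md` for assumptions
and parameter provenance.

## Worked example

```python
from adcpbpk import AdcPbpkModel, build_regimen

model = AdcPbpkModel(species="human")
result = model.simulate(build_regimen("Q3W", 2.4, n_cycles=3), t_end=63.0)
print(result.summary())
```

```
ADC PBPK simulation — human
  regimen: 2.4 mg/kg at days [0.0, 21.0, 42.0]
  horizon: 63.0 d, 144 states, dar_mode=pooled
  plasma AUC total mAb:          719 ug/mL*day
  plasma AUC conjugated MMAE:    1.314e+04 ng/mL*day
  plasma AUC unconjugated MMAE:  59.2 ng/mL*day
  final DAR: 3.354 (DAR0 4.0)
  mass balance: mAb 1.77e-11, payload 1.38e-09
```

Three 2.4 mg/kg doses every three weeks: the antibody AUC corresponds to a
clearance of ~16 mL/day/kg-scale ADC kinetics, free MMAE stays three orders
of magnitude below the conjugated payload, the average DAR declines only
slowly in human (SF = 0.1) and is pushed back toward 4 by each fresh dose,
and the mass-balance audit confirms the integrator honors the payload
conservation identity to ~1e-9.

Tissue trajectories are in `result.to_frame()`; `result.ledgers()` carries
the cumulative release/elimination pathways;
`metrics.payload_source_attribution(result, basis="plasma")` splits plasma
free-MMAE exposure by originating pathway. The same run from a shell:

```bash
adcpbpk simulate --species human --regimen Q3W --dose 2.4 --n-cycles 3 \
        --t-end 63 --out human_q3w.csv
```

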