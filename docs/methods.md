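# Methods

`adcpbpk` simulates the whole-body pharmacokinetics of vc-MMAE antibody-drug
conjugates (ADCs) by coupling two physiologically-based models — one for the
antibody component, one for the free payload — through drug-to-antibody-ratio
(DAR) dependent deconjugation and degradation-driven payload release. This
note records the model structure, its assumptions, the parameter choices that
matter, the numerical decisions, and the known limitations.

## Model structure

**Circulation.** Fifteen perfused organ compartments (lung, heart, kidney,
muscle, skin, liver, brain, fat, thymus, bone, small and large intestine,
spleen, pancreas, and a mass-closing "other") plus central blood and a single
lymph-node pool. The blood pool feeds the lung in series; the lung outflow
perfuses the remaining organs in parallel; splanchnic organs (spleen,
intestines, pancreas) drain into the liver inflow. Every organ is divided
into plasma, blood-cell, endosomal, interstitial and cellular
sub-compartments.

**Antibody.** Per organ the antibody occupies vascular, endosomal-unbound,
endosomal-FcRn-bound and interstitial states. Transport: convection with
plasma flow; transcapillary filtration `L(1−σ_v)C_v` and lymphatic drainage
`L(1−σ_i)C_i` through a common lymph-node pool; fluid-phase pinocytosis at
rate `CL_up` per unit endosomal volume drawing symmetrically from the
vascular and interstitial sides; kinetic FcRn binding (`kon`, `koff`); exit
of the bound pool at the pinocytosis rate split `FR` to recycling and `1−FR`
to transcytosis; first-order lysosomal degradation (`kdeg`) of the unbound
endosomal pool. Free FcRn is computed algebraically as
`FcRn_total − bound`, so receptor conservation holds to machine precision.

**Payload (MMAE).** Rapid distribution among plasma, endothelium and
interstitium is represented by lumping those volumes into one extracellular
pool per organ. Exchange with blood cells and the cellular space is
permeability-limited (`PS` terms) with partition coefficients `Kp_BC` and
`Kp` setting equilibria; blood cells travel with hematocrit-weighted regional
flow. Hepatic clearance of unbound payload in the liver extracellular pool
(`CLint · BW · 0.06 · fup`, L/h) is the only elimination route; biliary
excretion and P-gp efflux are deliberately absent.

**Coupling.** The average DAR declines by nonspecific deconjugation with an
empirical DAR-dependent rate

    k_dec(DAR) = (α − (α−β)·DAR^(−τ) / (F + DAR^(−τ))) · SF,
    dDAR/dt    = −k_dec(DAR) · DAR,

with α = 0.0806 d⁻¹, β = 0.0102 d⁻¹, F = 0.282, τ = 5.68, interpolating
between a fast high-DAR and a slow low-DAR regime (the observed biphasic DAR
decline). `SF` scales the rate between species by allometry,
`SF = (BW/BW_mouse)^(−0.25)`, reported to one decimal: 1 (mouse), 0.6 (rat),
0.3 (monkey), 0.1 (human). Deconjugation releases free payload from every
antibody-containing pool at `k_dec·DAR·amount`; each antibody degraded in an
endosome releases `DAR` payload molecules into that tissue's cellular space.
Degradation of the ADC is faster than of the naked antibody by the
species fold-change `f_Kdeg` (1, 1, 3, 4 for mouse, rat, monkey, human),
reflecting conjugation-enhanced clearance in higher species.

Because deconjugation acts on *all* antibody pools (including central blood
and the lymph node), the global DAR balance closes exactly:
`conjugated + free + eliminated = DAR0 × dosed payload` is an identity of
the equations, and the mass-balance audit checks the integrator against it.

**Multi-dose DAR.** A fresh dose carries DAR0 and raises the circulating
average; the model therefore resets the DAR state amount-weighted at each
bolus, `DAR ← (DAR·A + DAR0·dose)/(A + dose)`, equivalent to tracking
conjugated-payload and antibody amounts and defining DAR as their ratio.
The alternative `per_cohort` mode gives each administration its own antibody
block and DAR ODE; the payload system is linear in its release fluxes, so
cohorts superpose exactly — this mode backs the superposition tests.

**Tumor (optional).** A single well-mixed tumor (default 2.5 cm diameter,
T2 category; void fraction 0.24) exchanges ADC and payload with plasma
(vascular exchange only, no lymphatics). Inside: reversible antigen binding,
internalization of the bound complex (receptor recycled, so
`free + bound = antigen_total` exactly with turnover off), intracellular
degradation releasing DAR-equivalent payload, and intra/extracellular payload
exchange. Antigen levels for the IHC grades (TNBC 2, 1+ 30, 2+ 150,
3+ 600 nM) and all tumor rates are **assumed defaults, not literature
transcriptions**, chosen to place receptor occupancy and tumor payload
kinetics in a physiologically sensible range; they are labeled as such in
the parameter files.

## Parameters

Species-printed values used exactly: body weights 0.028/0.28/6.2/70 kg;
MMAE plasma protein binding fup 20.0/87.5/18.0/76.7 % (the 18 % monkey value,
which predicted better than the alternative 65 %); blood-cell partition
Kp_BC 5.46/4.00/3.00/1.34; intrinsic clearance CLint 67.7/16.4/33.6/2.35
mL/min/kg (rat hepatocytes, monkey microsomes, human hepatocytes — the
sources that predicted best); FcRn kon 0.0806/0.800/0.792/0.559 nM⁻¹h⁻¹ and
koff 6.55/144/46.8/23.9 h⁻¹; `f_Kdeg` 1/1/3/4; SF 1/0.6/0.3/0.1.

Values the platform supplement houses but the available text does not print
are shipped as documented defaults: per-tissue volumes and flows built from
standard PBPK composition data (fractional organ weights, allometric cardiac
output `14.1·BW^0.75` L/h blood, hematocrit 0.45, lymph flow 0.2 % of plasma
flow, endosomal space 0.5 % of organ volume, σ_i = 0.2, σ_v 0.85–0.99 by
capillary type); antibody cell biology `FR = 0.715`, `CL_up = 0.55 h⁻¹`,
`FcRn_total = 49,800 nM`, naked-antibody `kdeg_base = 30 h⁻¹` (chosen once so
the naked-antibody clearance sits at a few mL/day/kg in human and the ADC
~3–4× higher); payload Kp and PS tables with header provenance flags. The
defaults matter for absolute concentration levels, not for any of the
structural identities (conservation, linearity, DAR kinetics, scaling rules)
the tests assert.

PS values are species-independent by default, matching the finding that
allometric PS scaling did not improve predictions; exponents 0.75 or 1 remain
available through `PayloadParameters.ps_allometric_exponent`.

Units: nM and hours internally; α/β are per day and cross one conversion
constant (`HOURS_PER_DAY`); doses in mg/kg and reported concentrations
(µg/mL antibody, ng/mL payload) are converted only at the boundaries
(default MW 150 kDa antibody, 717.98 Da MMAE).

## Numerics

Stiff integration by `scipy.integrate.solve_ivp` (BDF; rtol 1e-8, atol
1e-12 nM), restarted at each IV bolus; if BDF stalls on a restart step (it
occasionally does when cohort blocks hold states of very different
magnitudes) the segment is retried with LSODA. Cumulative ledgers (releases
by pathway, degradation, hepatic elimination) are integrated as extra states,
so audits compare solver output against exact identities rather than
post-hoc quadrature. Tightening tolerances tenfold moves plasma AUCs by
well under 0.1 %.

The deconjugation rate is evaluated as `α − (α−β)/(F·DAR^τ + 1)`,
algebraically identical to the published form but stable as DAR → 0 (it
returns the β asymptote without special-casing).

`fit_sf` recovers SF by bounded deterministic scalar minimization of the
residual sum of squares between the integrated DAR ODE and observed DAR
points; noise-free recovery is exact to optimizer tolerance, and with 10 %
multiplicative noise on eight points the estimate stays within 20 % of truth
in ≥ 90 % of seeded replicates.

**Linearity.** The kinetic FcRn balance makes the antibody block mildly
nonlinear: at 3 mg/kg in rat, endosomal receptor occupancy peaks near 0.8 %,
deflecting trajectories ~0.3 % from dose-proportionality (independent of
solver tolerance). Dose-linearity invariants are therefore asserted in the
receptor-excess regime (≤ 0.05 mg/kg), where the system is linear to solver
accuracy; superposition is asserted in per-cohort mode, where it is exact at
clinical doses.

**Payload source attribution** has two bases. The ledger (`generation`)
basis attributes cumulative release by pathway — cheap, but it counts
tissue-released payload the moment it appears inside cells, so degradation
dominates from the first hours. The `plasma` basis attributes cumulative
plasma exposure by re-simulating with one source group enabled at a time
(valid because the payload subsystem is linear in its sources); there,
plasma deconjugation dominates the first hours after a human dose and tissue
release becomes the predominant, sustained source — the physiologically
meaningful reading, and the one the qualitative tests assert.

## What the synthetic data emulate — and what they do not

`FixtureSpec`/`generate_fixture` mimic pooled multi-study digitized data:
six studies, doses cycling through 5/10/20 mg/kg (rat), nine sampling times
to 42 days, multiplicative lognormal noise with 30 % CV and *unit mean* (so
pooled means are unbiased), all under one seed. Real digitized datasets add
features the generator omits: assay-specific bias between analytes,
inter-ADC differences collapsed by dose normalization, censoring below
quantification limits, and digitization error correlated within a profile.
Passing tests on fixtures therefore demonstrate estimator and pipeline
correctness — not predictive accuracy against real observed data, which
would require the original digitized profiles.

## Problem sizes used in tests

Simulations in the test-suite use the study species and regimens at modest
horizons: rat single-dose runs of 14–42 days, the human 2.4 mg/kg Q3W course
over 63 days (three cycles), tumor runs across all four IHC grades, and 500
replicate fixtures for sparse-AUC coverage. The full suite completes in
about a minute on one core.

## Known limitations

* Tissue TMDD, P-gp efflux, biliary excretion and enterohepatic
  recirculation are excluded by design; infusion kinetics are not modeled
  (bolus only).
* Conjugated antibody is not an analyte distinct from total antibody — the
  average-DAR formulation collapses them.
* Individual DAR species (DAR0…DAR8) are not tracked; deconjugated antibody
  retains the disposition of conjugated antibody.
* The tumor is well-mixed: no Krogh-cylinder gradients, no growth/shrinkage,
  no bystander pharmacodynamics.
* Physiology, Kp/PS and tumor values are documented defaults where the
  source supplement is unavailable; absolute tissue concentration
  predictions should be read as platform behavior, not validated
  species-specific predictions.
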