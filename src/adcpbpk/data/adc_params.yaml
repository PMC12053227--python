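# Species-specific pharmacokinetic parameters for a vc-MMAE ADC.
#
# fup, Kp_BC, CLint, FcRn kon/koff, f_Kdeg and the deconjugation-rate
# coefficients are transcribed model values (CLint source: rat hepatocytes,
# monkey liver microsomes, human hepatocytes; monkey fup: the 18% literature
# value that gave the better prediction). CL_up, FR, kdeg_base and DAR0 are
# platform-informed assumed defaults; see docs/methods.md.

deconjugation:
  alpha: 0.0806        # 1/day, high-DAR asymptote
  beta: 0.0102         # 1/day, low-DAR asymptote
  F: 0.282             # shape constant
  tau: 5.68            # Hill-like exponent
  reference_weight: 0.028   # kg (mouse), allometric reference for SF
  exponent: -0.25

coupling:
  DAR0: 4.0
  MW_mAb: 150000.0     # g/mol
  MW_MMAE: 717.98      # g/mol

mab_shared:
  CL_up: 0.55          # 1/h per unit endosomal volume (assumed default)
  FR: 0.715            # fraction of FcRn-bound mAb recycled to vascular space
  kdeg_base: 30.0      # 1/h, lysosomal degradation of FcRn-unbound mAb (assumed default)

species:
  mouse:
    fup: 0.200
    Kp_BC: 5.46
    CLint: 67.7        # mL/min/kg
    kon_FcRn: 0.0806   # 1/nM/h
    koff_FcRn: 6.55    # 1/h
    f_Kdeg: 1.0
  rat:
    fup: 0.875
    Kp_BC: 4.00
    CLint: 16.4
    kon_FcRn: 0.800
    koff_FcRn: 144.0
    f_Kdeg: 1.0
  monkey:
    fup: 0.180
    Kp_BC: 3.00
    CLint: 33.6
    kon_FcRn: 0.792
    koff_FcRn: 46.8
    f_Kdeg: 3.0
  human:
    fup: 0.767
    Kp_BC: 1.34
    CLint: 2.35
    kon_FcRn: 0.559
    koff_FcRn: 23.9
    f_Kdeg: 4.0
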