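# physiology table constructed from standard PBPK composition data
# (fractional organ volumes/flows, allometric cardiac output 14.1*BW^0.75 L/h blood);
# lymph flow = 0.2% of plasma flow per tissue; endosomal space = 0.5% of tissue volume;
# assumed defaults where the platform supplementary tables are not printed
# volumes in L, flows in L/h, reflection coefficients dimensionless
#!species = mouse
#!body_weight = 0.028
#!hematocrit = 0.45
#!FcRn_total = 49800.0
#!V_blood_plasma = 0.0007218134
#!V_blood_cell = 0.0005905746
#!V_lymphnode = 5.6e-05
tissue,V_plasma,V_bloodcell,V_endosomal,V_interstitial,V_cellular,Q_plasma,L_lymph,sigma_v,sigma_i
lung,4.4044e-05,3.6036e-05,1.54e-06,5.852e-05,0.00016786,0.5308237255,0.001061647451,0.95,0.2
heart,5.39e-06,4.41e-06,7e-07,2.24e-05,0.0001071,0.021232949,4.2465898e-05,0.95,0.2
kidney,1.5246e-05,1.2474e-05,1.26e-06,5.04e-05,0.00017262,0.0902400333,0.000180480067,0.9,0.2
muscle,0.00011704,9.576e-05,5.32e-05,0.0012768,0.0090972,0.0902400333,0.000180480067,0.95,0.2
skin,4.158e-05,3.402e-05,1.26e-05,0.000882,0.0015498,0.0307877761,6.1575552e-05,0.95,0.2
liver,4.4044e-05,3.6036e-05,3.64e-06,0.0001456,0.00049868,0.0345035422,6.9007084e-05,0.85,0.2
brain,5.082e-06,4.158e-06,1.54e-06,1.232e-06,0.000295988,0.0610447284,0.000122089457,0.99,0.2
fat,1.54e-05,1.26e-05,1.4e-05,0.000378,0.00238,0.0265411863,5.3082373e-05,0.95,0.2
thymus,3.234e-07,2.646e-07,9.8e-08,2.94e-06,1.5974e-05,0.0063698847,1.2739769e-05,0.95,0.2
bone,6.16e-05,5.04e-05,1.4e-05,0.00028,0.002394,0.0265411863,5.3082373e-05,0.85,0.2
small_intestine,5.6056e-06,4.5864e-06,1.274e-06,4.8412e-05,0.000194922,0.0530823725,0.000106164745,0.9,0.2
large_intestine,3.2648e-06,2.6712e-06,7.42e-07,2.8196e-05,0.000113526,0.021232949,4.2465898e-05,0.9,0.2
spleen,8.8088e-06,7.2072e-06,3.64e-07,1.456e-05,4.186e-05,0.0106164745,2.1232949e-05,0.85,0.2
pancreas,1.078e-06,8.82e-07,1.96e-07,6.664e-06,3.038e-05,0.0053082373,1.0616475e-05,0.9,0.2
other,1.848e-05,1.512e-05,5.6e-06,0.000168,0.0009128,0.0530823725,0.000106164745,0.95,0.2
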