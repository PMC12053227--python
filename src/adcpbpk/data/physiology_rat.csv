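# physiology table constructed from standard PBPK composition data
# (fractional organ volumes/flows, allometric cardiac output 14.1*BW^0.75 L/h blood);
# lymph flow = 0.2% of plasma flow per tissue; endosomal space = 0.5% of tissue volume;
# assumed defaults where the platform supplementary tables are not printed
# volumes in L, flows in L/h, reflection coefficients dimensionless
#!species = rat
#!body_weight = 0.28
#!hematocrit = 0.45
#!FcRn_total = 49800.0
#!V_blood_plasma = 0.007218134
#!V_blood_cell = 0.005905746
#!V_lymphnode = 0.00056
tissue,V_plasma,V_bloodcell,V_endosomal,V_interstitial,V_cellular,Q_plasma,L_lymph,sigma_v,sigma_i
lung,0.00044044,0.00036036,1.54e-05,0.0005852,0.0016786,2.9850411722,0.005970082344,0.95,0.2
heart,5.39e-05,4.41e-05,7e-06,0.000224,0.001071,0.1194016469,0.000238803294,0.95,0.2
kidney,0.00015246,0.00012474,1.26e-05,0.000504,0.0017262,0.5074569993,0.001014913999,0.9,0.2
muscle,0.0011704,0.0009576,0.000532,0.012768,0.090972,0.5074569993,0.001014913999,0.95,0.2
skin,0.0004158,0.0003402,0.000126,0.00882,0.015498,0.173132388,0.000346264776,0.95,0.2
liver,0.00044044,0.00036036,3.64e-05,0.001456,0.0049868,0.1940276762,0.000388055352,0.85,0.2
brain,5.082e-05,4.158e-05,1.54e-05,1.232e-05,0.00295988,0.3432797348,0.00068655947,0.99,0.2
fat,0.000154,0.000126,0.00014,0.00378,0.0238,0.1492520586,0.000298504117,0.95,0.2
thymus,3.234e-06,2.646e-06,9.8e-07,2.94e-05,0.00015974,0.0358204941,7.1640988e-05,0.95,0.2
bone,0.000616,0.000504,0.00014,0.0028,0.02394,0.1492520586,0.000298504117,0.85,0.2
small_intestine,5.6056e-05,4.5864e-05,1.274e-05,0.00048412,0.00194922,0.2985041172,0.000597008234,0.9,0.2
large_intestine,3.2648e-05,2.6712e-05,7.42e-06,0.00028196,0.00113526,0.1194016469,0.000238803294,0.9,0.2
spleen,8.8088e-05,7.2072e-05,3.64e-06,0.0001456,0.0004186,0.0597008234,0.000119401647,0.85,0.2
pancreas,1.078e-05,8.82e-06,1.96e-06,6.664e-05,0.0003038,0.0298504117,5.9700823e-05,0.9,0.2
other,0.0001848,0.0001512,5.6e-05,0.00168,0.009128,0.2985041172,0.000597008234,0.95,0.2
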