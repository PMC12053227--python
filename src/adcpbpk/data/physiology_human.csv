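# physiology table constructed from standard PBPK composition data
# (fractional organ volumes/flows, allometric cardiac output 14.1*BW^0.75 L/h blood);
# lymph flow = 0.2% of plasma flow per tissue; endosomal space = 0.5% of tissue volume;
# assumed defaults where the platform supplementary tables are not printed
# volumes in L, flows in L/h, reflection coefficients dimensionless
#!species = human
#!body_weight = 70.0
#!hematocrit = 0.45
#!FcRn_total = 49800.0
#!V_blood_plasma = 1.8045335
#!V_blood_cell = 1.4764365
#!V_lymphnode = 0.14
tissue,V_plasma,V_bloodcell,V_endosomal,V_interstitial,V_cellular,Q_plasma,L_lymph,sigma_v,sigma_i
lung,0.11011,0.09009,0.00385,0.1463,0.41965,187.6745279429,0.375349055886,0.95,0.2
heart,0.013475,0.011025,0.00175,0.056,0.26775,7.5069811177,0.015013962235,0.95,0.2
kidney,0.038115,0.031185,0.00315,0.126,0.43155,31.9046697503,0.063809339501,0.9,0.2
muscle,0.2926,0.2394,0.133,3.192,22.743,31.9046697503,0.063809339501,0.95,0.2
skin,0.10395,0.08505,0.0315,2.205,3.8745,10.8851226207,0.021770245241,0.95,0.2
liver,0.11011,0.09009,0.0091,0.364,1.2467,12.1988443163,0.024397688633,0.85,0.2
brain,0.012705,0.010395,0.00385,0.00308,0.73997,21.5825707134,0.043165141427,0.99,0.2
fat,0.0385,0.0315,0.035,0.945,5.95,9.3837263971,0.018767452794,0.95,0.2
thymus,0.0008085,0.0006615,0.000245,0.00735,0.039935,2.2520943353,0.004504188671,0.95,0.2
bone,0.154,0.126,0.035,0.7,5.985,9.3837263971,0.018767452794,0.85,0.2
small_intestine,0.014014,0.011466,0.003185,0.12103,0.487305,18.7674527943,0.037534905589,0.9,0.2
large_intestine,0.008162,0.006678,0.001855,0.07049,0.283815,7.5069811177,0.015013962235,0.9,0.2
spleen,0.022022,0.018018,0.00091,0.0364,0.10465,3.7534905589,0.007506981118,0.85,0.2
pancreas,0.002695,0.002205,0.00049,0.01666,0.07595,1.8767452794,0.003753490559,0.9,0.2
other,0.0462,0.0378,0.014,0.42,2.282,18.7674527943,0.037534905589,0.95,0.2
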