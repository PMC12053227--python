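# physiology table constructed from standard PBPK composition data
# (fractional organ volumes/flows, allometric cardiac output 14.1*BW^0.75 L/h blood);
# lymph flow = 0.2% of plasma flow per tissue; endosomal space = 0.5% of tissue volume;
# assumed defaults where the platform supplementary tables are not printed
# volumes in L, flows in L/h, reflection coefficients dimensionless
#!species = monkey
#!body_weight = 6.2
#!hematocrit = 0.45
#!FcRn_total = 49800.0
#!V_blood_plasma = 0.15983011
#!V_blood_cell = 0.13077009
#!V_lymphnode = 0.0124
tissue,V_plasma,V_bloodcell,V_endosomal,V_interstitial,V_cellular,Q_plasma,L_lymph,sigma_v,sigma_i
lung,0.0097526,0.0079794,0.000341,0.012958,0.037169,30.470218552,0.060940437104,0.95,0.2
heart,0.0011935,0.0009765,0.000155,0.00496,0.023715,1.2188087421,0.002437617484,0.95,0.2
kidney,0.0033759,0.0027621,0.000279,0.01116,0.038223,5.1799371538,0.010359874308,0.9,0.2
muscle,0.025916,0.021204,0.01178,0.28272,2.01438,5.1799371538,0.010359874308,0.95,0.2
skin,0.009207,0.007533,0.00279,0.1953,0.34317,1.767272676,0.003534545352,0.95,0.2
liver,0.0097526,0.0079794,0.000806,0.03224,0.110422,1.9805642059,0.003961128412,0.85,0.2
brain,0.0011253,0.0009207,0.000341,0.0002728,0.0655402,3.5040751335,0.007008150267,0.99,0.2
fat,0.00341,0.00279,0.0031,0.0837,0.527,1.5235109276,0.003047021855,0.95,0.2
thymus,7.161e-05,5.859e-05,2.17e-05,0.000651,0.0035371,0.3656426226,0.000731285245,0.95,0.2
bone,0.01364,0.01116,0.0031,0.062,0.5301,1.5235109276,0.003047021855,0.85,0.2
small_intestine,0.00124124,0.00101556,0.0002821,0.0107198,0.0431613,3.0470218552,0.00609404371,0.9,0.2
large_intestine,0.00072292,0.00059148,0.0001643,0.0062434,0.0251379,1.2188087421,0.002437617484,0.9,0.2
spleen,0.00195052,0.00159588,8.06e-05,0.003224,0.009269,0.609404371,0.001218808742,0.85,0.2
pancreas,0.0002387,0.0001953,4.34e-05,0.0014756,0.006727,0.3047021855,0.000609404371,0.9,0.2
other,0.004092,0.003348,0.00124,0.0372,0.20212,3.0470218552,0.00609404371,0.95,0.2
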