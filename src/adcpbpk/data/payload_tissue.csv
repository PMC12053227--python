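# payload tissue parameters: Kp (cell:extracellular partition, dimensionless),
# PS_cell and PS_BC (permeability-surface-area products, L/h).
# ASSUMED DEFAULTS, not transcribed values: the source supplementary table is
# not printed in the platform publication. PS values are species-independent
# by default (allometric scaling available via configuration).
tissue,Kp,PS_cell,PS_BC
lung,6.0,0.0185845,0.039897
heart,4.0,0.0118575,0.0048825
kidney,15.0,0.0191115,0.0138105
muscle,3.0,1.00719,0.10602
skin,4.0,0.171585,0.037665
liver,18.0,0.055211,0.039897
brain,0.3,0.0327701,0.0046035
fat,2.0,0.2635,0.01395
thymus,4.0,0.00176855,0.00029295
bone,3.0,0.26505,0.0558
small_intestine,8.0,0.02158065,0.0050778
large_intestine,8.0,0.01256895,0.0029574
spleen,10.0,0.0046345,0.0079794
pancreas,5.0,0.0033635,0.0009765
other,4.0,0.10106,0.01674
blood,1.0,0.0,0.65385045
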