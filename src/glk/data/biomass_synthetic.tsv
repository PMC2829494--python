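# SYNTHETIC biomass composition example (growth-precursor consumption
# proportions, arbitrary demo network ids).  Real analyses should supply the
# composition table of their reconstruction (e.g. an iND750-style table).
metabolite_id	coefficient
atp	59.276
g6p	1.071
f6p	0.243
pyruvate	2.904
pep	0.519
glycerol_3p	0.142
nad	0.00567
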