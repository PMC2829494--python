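# Selected yeast intracellular metabolite concentrations (mM)
metabolite_id	mM	source	origin	metabolite_name
bpg13	2.75e-4	organism-match	biomodels.db:release11	3-Phospho-D-glyceroyl phosphate
glycerate_2p	0.0371	organism-match	biomodels.db:release11	D-Glycerate 2-phosphate
glycerate_3p	0.278	organism-match	biomodels.db:release11	3-Phospho-D-glycerate
acetaldehyde	0.17	organism-match	biomodels.db:release11	Acetaldehyde
adp	1.63	organism-match	biomodels.db:release11	ADP
amp	0.796	organism-match	biomodels.db:release11	AMP
atp	1.13	organism-match	biomodels.db:release11	ATP
co2	1	organism-match	biomodels.db:release11	CO2
dhap	0.59	organism-match	biomodels.db:release11	Dihydroxyacetone phosphate
ethanol	50	organism-match	biomodels.db:release11	Ethanol
f26bp	0.02	organism-match	biomodels.db:release11	D-Fructose 2,6-bisphosphate
f6p	0.112	organism-match	biomodels.db:release11	D-Fructose 6-phosphate
fbp	2.82	organism-match	biomodels.db:release11	D-Fructose 1,6-bisphosphate
g3p	0.069	organism-match	biomodels.db:release11	Glyceraldehyde 3-phosphate
g6p	1.02	organism-match	biomodels.db:release11	D-Glucose 6-phosphate
glucose	0.0906	organism-match	biomodels.db:release11	D-Glucose
glycerol	2.27	organism-match	biomodels.db:release11	Glycerol
glycerol_3p	0.457	organism-match	biomodels.db:release11	Glycerol 3-phosphate
nad	1.5	organism-match	biomodels.db:release11	Nicotinamide adenine dinucleotide
nadh	0.0861	organism-match	biomodels.db:release11	Nicotinamide adenine dinucleotide - reduced
pep	0.0302	organism-match	biomodels.db:release11	Phosphoenolpyruvate
pyruvate	8.36	organism-match	biomodels.db:release11	Pyruvate
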