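# Extracellular metabolite concentrations of the metabolic-footprinting medium (mM)
metabolite_id	mM	source	origin	metabolite_name
aminobenzoate_4_e	0.0015	organism-match	footprinting-medium	4-Aminobenzoate
arginine_e	1	organism-match	footprinting-medium	L-Arginine
aspartate_e	1	organism-match	footprinting-medium	L-Aspartate
biotin_e	8.2e-5	organism-match	footprinting-medium	Biotin
citrate_e	1	organism-match	footprinting-medium	Citrate
fumarate_e	1	organism-match	footprinting-medium	Fumarate
glucose_e	11.1	organism-match	footprinting-medium	D-Glucose
glutamate_e	1	organism-match	footprinting-medium	L-Glutamate
histidine_e	1	organism-match	footprinting-medium	L-Histidine
inositol_e	0.055	organism-match	footprinting-medium	myo-Inositol
potassium_e	7.11	organism-match	footprinting-medium	potassium
leucine_e	1	organism-match	footprinting-medium	L-Leucine
lysine_e	1	organism-match	footprinting-medium	L-Lysine
malate_e	1	organism-match	footprinting-medium	L-Malate
methionine_e	1	organism-match	footprinting-medium	L-Methionine
sodium_e	1.71	organism-match	footprinting-medium	Sodium
ammonium_e	38	organism-match	footprinting-medium	Ammonium
pantothenate_e	0.0042	organism-match	footprinting-medium	(R)-Pantothenate
pyridoxine_e	0.0019	organism-match	footprinting-medium	Pyridoxine
pyruvate_e	1	organism-match	footprinting-medium	Pyruvate
riboflavin_e	5.3e-4	organism-match	footprinting-medium	Riboflavin
serine_e	1	organism-match	footprinting-medium	L-Serine
sulfate_e	42.2	organism-match	footprinting-medium	Sulfate
succinate_e	1	organism-match	footprinting-medium	Succinate
thiamin_e	0.0012	organism-match	footprinting-medium	Thiamin
threonine_e	1	organism-match	footprinting-medium	L-Threonine
tryptophan_e	1	organism-match	footprinting-medium	L-Tryptophan
valine_e	1	organism-match	footprinting-medium	L-Valine
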