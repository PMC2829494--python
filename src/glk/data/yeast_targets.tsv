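# Selected yeast reaction fluxes curated from kinetic-model repositories (mM/s)
reaction_id	flux_mM_s	source	origin	reaction_name
acetaldehyde_transport	0.00141	organism-match	biomodels.db:release11	acetaldehyde transport
adenylate_kinase	0	organism-match	biomodels.db:release11	adenylate kinase
alcohol_dehydrogenase_rev	1.17	organism-match	biomodels.db:release11	alcohol dehydrogenase, reverse rxn (acetaldehyde -> ethanol)
atpase_cytosolic	0.595	organism-match	biomodels.db:release11	ATPase, cytosolic
enolase	1.76	organism-match	biomodels.db:release11	enolase
ethanol_transport	0.0134	organism-match	biomodels.db:release11	ethanol transport
fructose_bisphosphate_aldolase	0.733	organism-match	biomodels.db:release11	fructose-bisphosphate aldolase
glycerol_3_phosphate_dehydrogenase_nad	0.149	organism-match	biomodels.db:release11	glycerol-3-phosphate dehydrogenase (NAD)
glycerol_3_phosphatase	0.051	organism-match	biomodels.db:release11	glycerol-3-phosphatase
glyceraldehyde_3_phosphate_dehydrogenase	1.06	organism-match	biomodels.db:release11	glyceraldehyde-3-phosphate dehydrogenase
glucose_transport_uniport	0.59	organism-match	biomodels.db:release11	glucose transport (uniport)
glycerol_transport_channel	0.00141	organism-match	biomodels.db:release11	glycerol transport via channel
hexokinase_d_glucose_atp	0.866	organism-match	biomodels.db:release11	hexokinase (D-glucose:ATP)
phosphofructokinase	0.606	organism-match	biomodels.db:release11	phosphofructokinase
glucose_6_phosphate_isomerase	0.733	organism-match	biomodels.db:release11	glucose-6-phosphate isomerase
phosphoglycerate_kinase	0.875	organism-match	biomodels.db:release11	phosphoglycerate kinase
phosphoglycerate_mutase	1.76	organism-match	biomodels.db:release11	phosphoglycerate mutase
pyruvate_kinase	1.06	organism-match	biomodels.db:release11	pyruvate kinase
pyruvate_decarboxylase	1.25	organism-match	biomodels.db:release11	pyruvate decarboxylase
triose_phosphate_isomerase	0.395	organism-match	biomodels.db:release11	triose-phosphate isomerase
trehalose_phosphate_synthase	0.04	organism-match	biomodels.db:release11	alpha, alpha-trehalose-phosphate synthase (UDP-forming)
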