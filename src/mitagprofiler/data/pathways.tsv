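pathway_id	name	required_genes
wood_ljungdahl	Wood-Ljungdahl pathway (reductive acetyl-CoA)	fhs,folD,metF,acsA,acsB,acsC,acsD,acsE
reductive_tca	Reductive citric acid cycle	aclA,aclB,mdh,fumA,fumB,frdA,frdB,sucC,sucD,korA,korB,icd,acnA
dissimilatory_sulfate_reduction	Dissimilatory sulphate reduction	sat,aprA,aprB,dsrA,dsrB,dsrC
assimilatory_sulfate_reduction	Assimilatory sulphate reduction	cysD,cysN,cysC,cysH,sir
thiosulfate_reduction	Polysulphide/thiosulphate reduction	phsA
assimilatory_nitrate_reduction	Assimilatory nitrate reduction	narB,nasA,nirA
dissimilatory_nitrate_reduction	Dissimilatory nitrate reduction to ammonium	napA,narG,narH,nirB,nirD
nitrogen_fixation	Nitrogen fixation (dinitrogenase)	nifD,nifK,nifH,anfG
nife_hydrogenase	Quinone-reactive NiFe hydrogenase	hydA,hydB
nadp_hydrogenase	NADP-reducing hydrogenase	hndB,hndC,hndD
arsenate_reduction	Arsenate reductase (glutaredoxin)	arsC
fumarate_respiration	Fumarate respiration	frdA,frdB
carboxydotrophy	Anaerobic CO oxidation	cooS
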