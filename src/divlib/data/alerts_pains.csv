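alert_id,smarts,description
pains_quinone,O=C1C=CC(=O)C=C1,para-quinone
pains_hydroquinone,Oc1ccc(O)cc1,hydroquinone
pains_catechol,Oc1ccccc1O,catechol
pains_rhodanine,S=C1NC(=O)CS1,rhodanine core
pains_azo,[#6]N=N[#6],azo compound
pains_phenol_hydrazone,Oc1ccccc1C=NN,hydroxyphenyl hydrazone
pains_alkylidene_barbiturate,C=C1C(=O)NC(=O)NC1=O,alkylidene barbiturate
pains_ene_one_ene,C=CC(=O)C=C,cross-conjugated dienone
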