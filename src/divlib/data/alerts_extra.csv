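alert_id,smarts,description
extra_phthalimide,O=C1c2ccccc2C(=O)N1,phthalimide
extra_naphthalene,c1ccc2ccccc2c1,naphthalene
extra_ester,[CX3](=O)[OX2][#6;!$([#6]=O)],carboxylic ester
extra_aryl_bromide,[Br]c,aryl bromide
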