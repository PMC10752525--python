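alert_id,smarts,description
aromatic_nitro,c[N+](=O)[O-],aromatic nitro group
acid_halide,[CX3](=O)[Cl],acid chloride / acyl halide
thioether,[#6][SX2;A][#6],dialkyl/arylalkyl thioether
sulfoxide,[#16X3](=[OX1])([#6])[#6],sulfoxide
aldehyde,[CX3H1](=O)[#6],aldehyde
alkyl_chloride,[CX4][Cl],reactive alkyl chloride
alkyl_bromide,[CX4][Br],alkyl bromide
isocyanate,[NX2]=[CX2]=[OX1],isocyanate
michael_acceptor,[CH2]=[CH][CX3]=[OX1],terminal vinyl carbonyl
epoxide,C1OC1,epoxide
anhydride,[CX3](=O)[OX2][CX3](=O),acid anhydride
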