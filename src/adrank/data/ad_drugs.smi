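# Twelve Alzheimer's-disease drug candidates, hydrogen-suppressed skeletons.
# Curated by drug name; each SMILES verified against the compound's known
# molecular formula (heavy-atom count) with rdkit.  Stereochemistry omitted:
# the downstream graph build ignores it.  Fixture version 1.
memantine	CC12CC3CC(C)(C1)CC(N)(C3)C2
rivastigmine	CCN(C)C(=O)Oc1cccc(C(C)N(C)C)c1
donepezil	COc1cc2c(cc1OC)C(=O)C(CC3CCN(CC3)Cc4ccccc4)C2
brexpiprazole	O=c1ccc2ccc(OCCCCN3CCN(c4cccc5ccsc45)CC3)cc2[nH]1
galantamine	COc1ccc2c3c1OC1CC(O)C=CC31CCN(C)C2
tacrine	Nc1c2c(nc3ccccc13)CCCC2
melatonin	CC(=O)NCCc1c[nH]c2ccc(OC)cc12
metacetamol	CC(=O)Nc1cccc(O)c1
curcumin	COc1cc(C=CC(=O)CC(=O)C=Cc2ccc(O)c(OC)c2)ccc1O
geniposide	COC(=O)C1=COC(OC2OC(CO)C(O)C(O)C2O)C2C1CC=C2CO
cryptotanshinone	CC1COC2=C1C(=O)C(=O)C1=C2C=CC2=C1CCCC2(C)C
gallic_acid	O=C(O)c1cc(O)c(O)c(O)c1
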