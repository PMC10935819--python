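methane	C
ethanol	CCO
benzene	c1ccccc1
toluene	Cc1ccccc1
phenol	Oc1ccccc1
aniline	Nc1ccccc1
pyridine	c1ccncc1
glucose	OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O
aspirin	CC(=O)Oc1ccccc1C(=O)O
caffeine	Cn1cnc2c1c(=O)n(C)c(=O)n2C
paracetamol	CC(=O)Nc1ccc(O)cc1
ibuprofen	CC(C)Cc1ccc(cc1)C(C)C(=O)O
naproxen	COc1ccc2cc(ccc2c1)C(C)C(=O)O
warfarin	CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O
diclofenac	OC(=O)Cc1ccccc1Nc1c(Cl)cccc1Cl
naloxone	Oc1ccc2CC3N(CC=C)CCC45C(Oc1c24)C(=O)CCC35O
atropine	CN1C2CCC1CC(C2)OC(=O)C(CO)c1ccccc1
lidocaine	CCN(CC)CC(=O)Nc1c(C)cccc1C
ketamine	CNC1(c2ccccc2Cl)CCCCC1=O
fluoxetine	CNCCC(Oc1ccc(cc1)C(F)(F)F)c1ccccc1
sertraline	CNC1CCC(c2ccc(Cl)c(Cl)c2)c2ccccc12
propranolol	CC(C)NCC(O)COc1cccc2ccccc12
atenolol	CC(C)NCC(O)COc1ccc(CC(N)=O)cc1
metoprolol	COCCc1ccc(OCC(O)CNC(C)C)cc1
citalopram	CN(C)CCCC1(OCc2cc(ccc12)C#N)c1ccc(F)cc1
venlafaxine	COc1ccc(cc1)C(CN(C)C)C1(O)CCCCC1
tramadol	CN(C)CC1CCCCC1(O)c1cccc(OC)c1
quinine	COc1ccc2nccc(C(O)C3CC4CCN3CC4C=C)c2c1
haloperidol	OC1(CCN(CCCC(=O)c2ccc(F)cc2)CC1)c1ccc(Cl)cc1
loratadine	CCOC(=O)N1CCC(=C2c3ccc(Cl)cc3CCc3cccnc23)CC1
sildenafil	CCCc1nn(C)c2c1nc([nH]c2=O)-c1cc(ccc1OCC)S(=O)(=O)N1CCN(C)CC1
celecoxib	Cc1ccc(cc1)-c1cc(nn1-c1ccc(cc1)S(N)(=O)=O)C(F)(F)F
losartan	CCCCc1nc(Cl)c(CO)n1Cc1ccc(cc1)-c1ccccc1-c1nnn[nH]1
valsartan	CCCCC(=O)N(Cc1ccc(cc1)-c1ccccc1-c1nnn[nH]1)C(C(C)C)C(=O)O
amlodipine	CCOC(=O)C1=C(COCCN)NC(C)=C(C1c1ccccc1Cl)C(=O)OC
omeprazole	COc1ccc2[nH]c(nc2c1)S(=O)Cc1ncc(C)c(OC)c1C
simvastatin	CCC(C)(C)C(=O)OC1CC(C)C=C2C=CC(C)C(CCC3CC(O)CC(=O)O3)C12
atorvastatin	CC(C)c1c(C(=O)Nc2ccccc2)c(-c2ccccc2)c(-c2ccc(F)cc2)n1CCC(O)CC(O)CC(=O)O
erythronolide	CCC1OC(=O)C(C)C(O)C(C)C(O)C(C)(O)CC(C)C(=O)C(C)C(O)C1C
branched_ester	CCC(C)C(=O)OC(C)C(C)C(O)C(C)CC(C)C
doxycycline	CC1c2cccc(O)c2C(=O)C2=C(O)C3(O)C(=O)C(=C(O)C(N(C)C)C3C(O)C12)C(N)=O
sterane_diol	CC1(C)C(O)CCC2(C)C1CCC1(C)C2CCC2C3CCC(O)C3(C)CCC12
biotin	OC(=O)CCCCC1SCC2NC(=O)NC12
cholesterol	CC(C)CCCC(C)C1CCC2C3CC=C4CC(O)CCC4(C)C3CCC12C
palmitic_acid	CCCCCCCCCCCCCCCC(=O)O
ciprofloxacin	OC(=O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O
levofloxacin	CC1COc2c(N3CCN(C)CC3)c(F)cc3c(=O)c(cn1c23)C(=O)O
indomethacin	COc1ccc2c(c1)c(CC(=O)O)c(C)n2C(=O)c1ccc(Cl)cc1
chlorpromazine	CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21
anilide_piperazine	Cc1ccc(NC(=O)c2ccc(CN3CCN(C)CC3)cc2)cc1Nc1nccc(-c2cccnc2)n1
cluster_analgesics	CC(C)Cc1ccc(cc1)C(C)C(=O)O.COc1ccc2cc(ccc2c1)C(C)C(=O)O.CC(=O)Nc1ccc(O)cc1.CC(=O)Oc1ccccc1C(=O)O.OC(=O)Cc1ccccc1Nc1c(Cl)cccc1Cl.CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O.CCN(CC)CC(=O)Nc1c(C)cccc1C.CNC1(c2ccccc2Cl)CCCCC1=O.CCO
cluster_cns	CNCCC(Oc1ccc(cc1)C(F)(F)F)c1ccccc1.CNC1CCC(c2ccc(Cl)c(Cl)c2)c2ccccc12.CN(C)CCCC1(OCc2cc(ccc12)C#N)c1ccc(F)cc1.COc1ccc(cc1)C(CN(C)C)C1(O)CCCCC1.CN(C)CC1CCCCC1(O)c1cccc(OC)c1.CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21.Cn1cnc2c1c(=O)n(C)c(=O)n2C
cluster_cardio	CC(C)NCC(O)COc1cccc2ccccc12.CC(C)NCC(O)COc1ccc(CC(N)=O)cc1.COCCc1ccc(OCC(O)CNC(C)C)cc1.CCOC(=O)C1=C(COCCN)NC(C)=C(C1c1ccccc1Cl)C(=O)OC.CCCCc1nc(Cl)c(CO)n1Cc1ccc(cc1)-c1ccccc1-c1nnn[nH]1.Cn1cnc2c1c(=O)n(C)c(=O)n2C
cluster_quinolones	OC(=O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O.CC1COc2c(N3CCN(C)CC3)c(F)cc3c(=O)c(cn1c23)C(=O)O.COc1ccc2c(c1)c(CC(=O)O)c(C)n2C(=O)c1ccc(Cl)cc1.COc1ccc2[nH]c(nc2c1)S(=O)Cc1ncc(C)c(OC)c1C.Cc1ccc(cc1)-c1cc(nn1-c1ccc(cc1)S(N)(=O)=O)C(F)(F)F.OC(=O)CCCCC1SCC2NC(=O)NC12.CCO
cluster_opioid_like	Oc1ccc2CC3N(CC=C)CCC45C(Oc1c24)C(=O)CCC35O.CN1C2CCC1CC(C2)OC(=O)C(CO)c1ccccc1.COc1ccc2nccc(C(O)C3CC4CCN3CC4C=C)c2c1.OC1(CCN(CCCC(=O)c2ccc(F)cc2)CC1)c1ccc(Cl)cc1.CCOC(=O)N1CCC(=C2c3ccc(Cl)cc3CCc3cccnc23)CC1.OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O.Cc1ccccc1
cluster_natural	CC(C)CCCC(C)C1CCC2C3CC=C4CC(O)CCC4(C)C3CCC12C.CCC(C)(C)C(=O)OC1CC(C)C=C2C=CC(C)C(CCC3CC(O)CC(=O)O3)C12.CCC1OC(=O)C(C)C(O)C(C)C(O)C(C)(O)CC(C)C(=O)C(C)C(O)C1C.CCCCCCCCCCCCCCCC(=O)O.CC(=O)Oc1ccccc1C(=O)O
cluster_small_pair	c1ccccc1.Oc1ccccc1.Nc1ccccc1.c1ccncc1.CCO
cluster_oversize	CC(C)c1c(C(=O)Nc2ccccc2)c(-c2ccccc2)c(-c2ccc(F)cc2)n1CCC(O)CC(O)CC(=O)O.Cc1ccc(NC(=O)c2ccc(CN3CCN(C)CC3)cc2)cc1Nc1nccc(-c2cccnc2)n1.CCCc1nn(C)c2c1nc([nH]c2=O)-c1cc(ccc1OCC)S(=O)(=O)N1CCN(C)CC1.CCCCC(=O)N(Cc1ccc(cc1)-c1ccccc1-c1nnn[nH]1)C(C(C)C)C(=O)O.CC1c2cccc(O)c2C(=O)C2=C(O)C3(O)C(=O)C(=C(O)C(N(C)C)C3C(O)C12)C(N)=O.CC1(C)C(O)CCC2(C)C1CCC1(C)C2CCC2C3CCC(O)C3(C)CCC12
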