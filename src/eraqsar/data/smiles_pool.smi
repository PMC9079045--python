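# Bundled pool of drug-like structures used as default templates by the
# synthetic activity-table generator. One SMILES per line, optional name.
CC(=O)Oc1ccccc1C(=O)O aspirin
CC(=O)Nc1ccc(O)cc1 paracetamol
Cn1cnc2c1c(=O)n(C)c(=O)n2C caffeine
CC(C)Cc1ccc(cc1)C(C)C(=O)O ibuprofen
COc1ccc2cc(ccc2c1)C(C)C(=O)O naproxen
CC12CCC3c4ccc(O)cc4CCC3C1CCC2O estradiol-like
CCC(=C(c1ccccc1)c1ccc(OCCN(C)C)cc1)c1ccccc1 tamoxifen
CCC(=C(CC)c1ccc(O)cc1)c1ccc(O)cc1 diethylstilbestrol
OC(=O)c1ccccc1O salicylic-acid
CCOC(=O)c1ccc(N)cc1 benzocaine
CCN(CC)CCOC(=O)c1ccc(N)cc1 procaine
CCN(CC)CC(=O)Nc1c(C)cccc1C lidocaine
CC(C)NCC(O)COc1cccc2ccccc12 propranolol
CC(C)NCC(O)COc1ccc(CC(N)=O)cc1 atenolol
CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O warfarin
CN1c2ccc(Cl)cc2C(=NCC1=O)c1ccccc1 diazepam
CN(C)CCC(c1ccc(Cl)cc1)c1ccccn1 chlorpheniramine
CN(C)CCOC(c1ccccc1)c1ccccc1 diphenhydramine
CN1CCCC1c1cccnc1 nicotine
NCCc1c[nH]c2ccc(O)cc12 serotonin
NCCc1ccc(O)c(O)c1 dopamine
CNCC(O)c1ccc(O)c(O)c1 adrenaline
CC(N)Cc1ccccc1 amphetamine
N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O tryptophan
N[C@@H](Cc1ccc(O)cc1)C(=O)O tyrosine
N[C@@H](Cc1ccccc1)C(=O)O phenylalanine
NC(=O)c1ccccc1 benzamide
CC(=O)Nc1ccccc1 acetanilide
O=c1ccc2ccccc2o1 coumarin
Oc1cc(O)c2c(c1)oc(-c1ccc(O)c(O)c1)c(O)c2=O quercetin
Oc1ccc(/C=C/c2cc(O)cc(O)c2)cc1 resveratrol
Oc1ccc(-c2coc3cc(O)cc(O)c3c2=O)cc1 genistein
CC(C)(c1ccc(O)cc1)c1ccc(O)cc1 bisphenol-A
CCC(=C(c1ccccc1)c1ccc(O)cc1)c1ccc(OCCN(C)C)cc1 hydroxytamoxifen
OC(=O)CCCc1ccc(N(CCCl)CCCl)cc1 chlorambucil
Nc1ccc(S(N)(=O)=O)cc1 sulfanilamide
Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1 sulfamethoxazole-like
COCCc1ccc(OCC(O)CNC(C)C)cc1 metoprolol
CC(C(=O)O)c1cccc(C(=O)c2ccccc2)c1 ketoprofen
CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1 fluoxetine
COc1ccc(C(CN(C)C)C2(O)CCCCC2)cc1 venlafaxine
COc1ccc2[nH]cc(CCNC(C)=O)c2c1 melatonin
Cn1c(=O)c2[nH]cnc2n(C)c1=O theophylline
O=C1NC(=O)C(c2ccccc2)(c2ccccc2)N1 phenytoin
NC(=O)N1c2ccccc2C=Cc2ccccc21 carbamazepine
Cc1ccc(C)c(OCCCC(C)(C)C(=O)O)c1 gemfibrozil
O=C1CC(c2ccc(O)cc2)Oc2cc(O)cc(O)c21 naringenin
Oc1ccc(-c2cc(=O)c3c(O)cc(O)cc3o2)cc1 apigenin
COc1cc(C=O)ccc1O vanillin
CC12CCC3c4ccc(O)cc4CCC3C1CCC2=O estrone-like
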