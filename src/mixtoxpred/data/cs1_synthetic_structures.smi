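CCNc1nc(NC(C)C)nc(Cl)n1	1912-24-9
CCNc1nc(NCC)nc(Cl)n1	122-34-9
CCNc1nc(NC(C)(C)C)nc(Cl)n1	5915-41-3
CC(C)Nc1nc(NC(C)C)nc(Cl)n1	139-40-2
CN(C)C(=O)Nc1ccc(Cl)c(Cl)c1	330-54-1
CC(C)c1ccc(NC(=O)N(C)C)cc1	34123-59-6
CON(C)C(=O)Nc1ccc(Cl)c(Cl)c1	330-55-2
CSC1=NN=C(C(C)(C)C)C(=O)N1N	21087-64-9
CCOP(=S)(OCC)Oc1nc(Cl)c(Cl)cc1Cl	2921-88-2
CCOP(=S)(OCC)Oc1cc(C)nc(C(C)C)n1	333-41-5
CCOC(=O)CC(SP(=S)(OC)OC)C(=O)OCC	121-75-5
CCOP(=S)(OCC)Oc1ccc(cc1)[N+](=O)[O-]	56-38-2
CNC(=O)Oc1cccc2ccccc12	63-25-2
CNC(=O)Oc1cccc2c1OC(C)(C)C2	1563-66-2
CNC(=O)ON=CC(C)(C)SC	116-06-3
CN(C)C(=O)Oc1nc(N(C)C)nc(C)c1C	23103-98-2
CCc1cccc(C)c1N(C(C)COC)C(=O)CCl	51218-45-2
CCc1cccc(CC)c1N(COC)C(=O)CCl	15972-60-8
CCC(CC)Nc1c([N+](=O)[O-])cc(C)c(C)c1[N+](=O)[O-]	40487-42-1
CCCN(CCC)c1c(cc(cc1[N+](=O)[O-])C(F)(F)F)[N+](=O)[O-]	1582-09-8
OC(=O)COc1ccc(Cl)cc1Cl	94-75-7
Cc1cc(Cl)ccc1OCC(=O)O	94-74-6
CC(Oc1ccc(Cl)cc1C)C(=O)O	93-65-2
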