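# one-letter code <TAB> residue unit SMILES (atom 0 = backbone N,
# backbone carbonyl C and O are the last two atoms)
G	NCC=O
A	NC(C)C=O
S	NC(CO)C=O
T	NC(C(O)C)C=O
C	NC(CS)C=O
V	NC(C(C)C)C=O
L	NC(CC(C)C)C=O
I	NC(C(C)CC)C=O
M	NC(CCSC)C=O
P	N1CCCC1C=O
F	NC(Cc1ccccc1)C=O
Y	NC(Cc1ccc(O)cc1)C=O
W	NC(Cc1c[nH]c2ccccc12)C=O
H	NC(Cc1c[nH]cn1)C=O
D	NC(CC(=O)O)C=O
E	NC(CCC(=O)O)C=O
N	NC(CC(N)=O)C=O
Q	NC(CCC(N)=O)C=O
K	NC(CCCCN)C=O
R	NC(CCCNC(=N)N)C=O
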