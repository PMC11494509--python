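residue_name,atom_name,charge,net_charge,note
ALA,N,-0.4157000000,0,synthetic stand-in
ALA,CA,0.0337000000,0,synthetic stand-in
ALA,C,0.5973000000,0,synthetic stand-in
ALA,O,-0.5679000000,0,synthetic stand-in
ALA,CB,0.3526000000,0,synthetic stand-in
ARG,N,-0.4157000000,1,synthetic stand-in
ARG,CA,0.0337000000,1,synthetic stand-in
ARG,C,0.5973000000,1,synthetic stand-in
ARG,O,-0.5679000000,1,synthetic stand-in
ARG,CB,0.0500000000,1,synthetic stand-in
ARG,CG,0.0500000000,1,synthetic stand-in
ARG,CD,0.0500000000,1,synthetic stand-in
ARG,NE,-0.5000000000,1,synthetic stand-in
ARG,CZ,0.4000000000,1,synthetic stand-in
ARG,NH1,-0.5000000000,1,synthetic stand-in
ARG,NH2,1.8026000000,1,synthetic stand-in
ASN,N,-0.4157000000,0,synthetic stand-in
ASN,CA,0.0337000000,0,synthetic stand-in
ASN,C,0.5973000000,0,synthetic stand-in
ASN,O,-0.5679000000,0,synthetic stand-in
ASN,CB,0.0500000000,0,synthetic stand-in
ASN,CG,0.0500000000,0,synthetic stand-in
ASN,OD1,-0.5500000000,0,synthetic stand-in
ASN,ND2,0.8026000000,0,synthetic stand-in
ASP,N,-0.4157000000,-1,synthetic stand-in
ASP,CA,0.0337000000,-1,synthetic stand-in
ASP,C,0.5973000000,-1,synthetic stand-in
ASP,O,-0.5679000000,-1,synthetic stand-in
ASP,CB,0.0500000000,-1,synthetic stand-in
ASP,CG,0.0500000000,-1,synthetic stand-in
ASP,OD1,-0.5500000000,-1,synthetic stand-in
ASP,OD2,-0.1974000000,-1,synthetic stand-in
CYM,N,-0.4157000000,-1,synthetic stand-in
CYM,CA,0.0337000000,-1,synthetic stand-in
CYM,C,0.5973000000,-1,synthetic stand-in
CYM,O,-0.5679000000,-1,synthetic stand-in
CYM,CB,0.0500000000,-1,synthetic stand-in
CYM,SG,-0.6974000000,-1,synthetic stand-in
CYS,N,-0.4157000000,0,synthetic stand-in
CYS,CA,0.0337000000,0,synthetic stand-in
CYS,C,0.5973000000,0,synthetic stand-in
CYS,O,-0.5679000000,0,synthetic stand-in
CYS,CB,0.0500000000,0,synthetic stand-in
CYS,SG,0.3026000000,0,synthetic stand-in
GLN,N,-0.4157000000,0,synthetic stand-in
GLN,CA,0.0337000000,0,synthetic stand-in
GLN,C,0.5973000000,0,synthetic stand-in
GLN,O,-0.5679000000,0,synthetic stand-in
GLN,CB,0.0500000000,0,synthetic stand-in
GLN,CG,0.0500000000,0,synthetic stand-in
GLN,CD,0.0500000000,0,synthetic stand-in
GLN,OE1,-0.5500000000,0,synthetic stand-in
GLN,NE2,0.7526000000,0,synthetic stand-in
GLU,N,-0.4157000000,-1,synthetic stand-in
GLU,CA,0.0337000000,-1,synthetic stand-in
GLU,C,0.5973000000,-1,synthetic stand-in
GLU,O,-0.5679000000,-1,synthetic stand-in
GLU,CB,0.0500000000,-1,synthetic stand-in
GLU,CG,0.0500000000,-1,synthetic stand-in
GLU,CD,0.0500000000,-1,synthetic stand-in
GLU,OE1,-0.5500000000,-1,synthetic stand-in
GLU,OE2,-0.2474000000,-1,synthetic stand-in
GLY,N,-0.4157000000,0,synthetic stand-in
GLY,CA,0.3863000000,0,synthetic stand-in
GLY,C,0.5973000000,0,synthetic stand-in
GLY,O,-0.5679000000,0,synthetic stand-in
HIS,N,-0.4157000000,0,synthetic stand-in
HIS,CA,0.0337000000,0,synthetic stand-in
HIS,C,0.5973000000,0,synthetic stand-in
HIS,O,-0.5679000000,0,synthetic stand-in
HIS,CB,0.0500000000,0,synthetic stand-in
HIS,CG,0.0500000000,0,synthetic stand-in
HIS,ND1,-0.5000000000,0,synthetic stand-in
HIS,CD2,0.0500000000,0,synthetic stand-in
HIS,CE1,0.0500000000,0,synthetic stand-in
HIS,NE2,0.6526000000,0,synthetic stand-in
ILE,N,-0.4157000000,0,synthetic stand-in
ILE,CA,0.0337000000,0,synthetic stand-in
ILE,C,0.5973000000,0,synthetic stand-in
ILE,O,-0.5679000000,0,synthetic stand-in
ILE,CB,0.0500000000,0,synthetic stand-in
ILE,CG1,0.0500000000,0,synthetic stand-in
ILE,CG2,0.0500000000,0,synthetic stand-in
ILE,CD1,0.2026000000,0,synthetic stand-in
LEU,N,-0.4157000000,0,synthetic stand-in
LEU,CA,0.0337000000,0,synthetic stand-in
LEU,C,0.5973000000,0,synthetic stand-in
LEU,O,-0.5679000000,0,synthetic stand-in
LEU,CB,0.0500000000,0,synthetic stand-in
LEU,CG,0.0500000000,0,synthetic stand-in
LEU,CD1,0.0500000000,0,synthetic stand-in
LEU,CD2,0.2026000000,0,synthetic stand-in
LYS,N,-0.4157000000,1,synthetic stand-in
LYS,CA,0.0337000000,1,synthetic stand-in
LYS,C,0.5973000000,1,synthetic stand-in
LYS,O,-0.5679000000,1,synthetic stand-in
LYS,CB,0.0500000000,1,synthetic stand-in
LYS,CG,0.0500000000,1,synthetic stand-in
LYS,CD,0.0500000000,1,synthetic stand-in
LYS,CE,0.0500000000,1,synthetic stand-in
LYS,NZ,1.1526000000,1,synthetic stand-in
MET,N,-0.4157000000,0,synthetic stand-in
MET,CA,0.0337000000,0,synthetic stand-in
MET,C,0.5973000000,0,synthetic stand-in
MET,O,-0.5679000000,0,synthetic stand-in
MET,CB,0.0500000000,0,synthetic stand-in
MET,CG,0.0500000000,0,synthetic stand-in
MET,SD,-0.3000000000,0,synthetic stand-in
MET,CE,0.5526000000,0,synthetic stand-in
PHE,N,-0.4157000000,0,synthetic stand-in
PHE,CA,0.0337000000,0,synthetic stand-in
PHE,C,0.5973000000,0,synthetic stand-in
PHE,O,-0.5679000000,0,synthetic stand-in
PHE,CB,0.0500000000,0,synthetic stand-in
PHE,CG,0.0500000000,0,synthetic stand-in
PHE,CD1,0.0500000000,0,synthetic stand-in
PHE,CD2,0.0500000000,0,synthetic stand-in
PHE,CE1,0.0500000000,0,synthetic stand-in
PHE,CE2,0.0500000000,0,synthetic stand-in
PHE,CZ,0.0526000000,0,synthetic stand-in
PRO,N,-0.4157000000,0,synthetic stand-in
PRO,CA,0.0337000000,0,synthetic stand-in
PRO,C,0.5973000000,0,synthetic stand-in
PRO,O,-0.5679000000,0,synthetic stand-in
PRO,CB,0.0500000000,0,synthetic stand-in
PRO,CG,0.0500000000,0,synthetic stand-in
PRO,CD,0.2526000000,0,synthetic stand-in
SER,N,-0.4157000000,0,synthetic stand-in
SER,CA,0.0337000000,0,synthetic stand-in
SER,C,0.5973000000,0,synthetic stand-in
SER,O,-0.5679000000,0,synthetic stand-in
SER,CB,0.0500000000,0,synthetic stand-in
SER,OG,0.3026000000,0,synthetic stand-in
THR,N,-0.4157000000,0,synthetic stand-in
THR,CA,0.0337000000,0,synthetic stand-in
THR,C,0.5973000000,0,synthetic stand-in
THR,O,-0.5679000000,0,synthetic stand-in
THR,CB,0.0500000000,0,synthetic stand-in
THR,OG1,-0.5500000000,0,synthetic stand-in
THR,CG2,0.8526000000,0,synthetic stand-in
TRP,N,-0.4157000000,0,synthetic stand-in
TRP,CA,0.0337000000,0,synthetic stand-in
TRP,C,0.5973000000,0,synthetic stand-in
TRP,O,-0.5679000000,0,synthetic stand-in
TRP,CB,0.0500000000,0,synthetic stand-in
TRP,CG,0.0500000000,0,synthetic stand-in
TRP,CD1,0.0500000000,0,synthetic stand-in
TRP,CD2,0.0500000000,0,synthetic stand-in
TRP,NE1,-0.5000000000,0,synthetic stand-in
TRP,CE2,0.0500000000,0,synthetic stand-in
TRP,CE3,0.0500000000,0,synthetic stand-in
TRP,CZ2,0.0500000000,0,synthetic stand-in
TRP,CZ3,0.0500000000,0,synthetic stand-in
TRP,CH2,0.4526000000,0,synthetic stand-in
TYR,N,-0.4157000000,0,synthetic stand-in
TYR,CA,0.0337000000,0,synthetic stand-in
TYR,C,0.5973000000,0,synthetic stand-in
TYR,O,-0.5679000000,0,synthetic stand-in
TYR,CB,0.0500000000,0,synthetic stand-in
TYR,CG,0.0500000000,0,synthetic stand-in
TYR,CD1,0.0500000000,0,synthetic stand-in
TYR,CD2,0.0500000000,0,synthetic stand-in
TYR,CE1,0.0500000000,0,synthetic stand-in
TYR,CE2,0.0500000000,0,synthetic stand-in
TYR,CZ,0.4000000000,0,synthetic stand-in
TYR,OH,-0.3474000000,0,synthetic stand-in
VAL,N,-0.4157000000,0,synthetic stand-in
VAL,CA,0.0337000000,0,synthetic stand-in
VAL,C,0.5973000000,0,synthetic stand-in
VAL,O,-0.5679000000,0,synthetic stand-in
VAL,CB,0.0500000000,0,synthetic stand-in
VAL,CG1,0.0500000000,0,synthetic stand-in
VAL,CG2,0.2526000000,0,synthetic stand-in
HOH,O,-0.8340000000,0,TIP3P
HOH,H1,0.4170000000,0,TIP3P
HOH,H2,0.4170000000,0,TIP3P
HOH,OW,-0.8340000000,0,TIP3P
HOH,HW1,0.4170000000,0,TIP3P
HOH,HW2,0.4170000000,0,TIP3P
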