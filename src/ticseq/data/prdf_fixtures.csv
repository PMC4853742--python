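residue,species,charge_class,peak_height,peak_pos,peak_width,depletion_depth,decay_length,noise_sd
ALA,K+,hydrophobic,0.4016,2.2706,0.9529,0.6850,3.8220,0.01
ALA,Cl-,hydrophobic,0.4016,2.2706,0.9529,0.6850,3.8220,0.01
ARG,K+,positive,1.0000,2.6000,1.2000,0.8310,4.2500,0.01
ARG,Cl-,positive,1.0000,2.6000,1.2000,0.4810,2.7500,0.01
ASN,K+,polar,0.4932,2.3647,1.0235,0.5387,3.0387,0.01
ASN,Cl-,polar,0.4932,2.3647,1.0235,0.5387,3.0387,0.01
ASP,K+,negative,0.9100,2.3412,1.0059,0.9380,5.1040,0.01
ASP,Cl-,negative,0.9100,2.3412,1.0059,1.2355,6.3790,0.01
CYS,K+,polar,0.5468,2.2941,0.9706,0.6884,3.7951,0.01
CYS,Cl-,polar,0.5468,2.2941,0.9706,0.6884,3.7951,0.01
GLN,K+,polar,0.4553,2.4353,1.0765,0.5300,2.9600,0.01
GLN,Cl-,polar,0.4553,2.4353,1.0765,0.5300,2.9600,0.01
GLU,K+,negative,0.8389,2.4118,1.0588,0.9060,4.9040,0.01
GLU,Cl-,negative,0.8389,2.4118,1.0588,1.1621,6.0014,0.01
GLY,K+,hydrophobic,0.4047,2.2000,0.9000,0.6064,3.3351,0.01
GLY,Cl-,hydrophobic,0.4047,2.2000,0.9000,0.6064,3.3351,0.01
HIS,K+,positive,0.6511,2.4588,1.0941,0.6694,3.5176,0.01
HIS,Cl-,positive,0.6511,2.4588,1.0941,0.5230,2.8900,0.01
ILE,K+,hydrophobic,0.4032,2.4824,1.1118,0.5290,2.9100,0.01
ILE,Cl-,hydrophobic,0.4032,2.4824,1.1118,0.5290,2.9100,0.01
LEU,K+,hydrophobic,0.4032,2.4824,1.1118,0.6233,3.3893,0.01
LEU,Cl-,hydrophobic,0.4032,2.4824,1.1118,0.6233,3.3893,0.01
LYS,K+,positive,0.9905,2.5529,1.1647,0.8855,4.4263,0.01
LYS,Cl-,positive,0.9905,2.5529,1.1647,0.5410,2.9500,0.01
MET,K+,hydrophobic,0.4411,2.4353,1.0765,0.5620,3.0480,0.01
MET,Cl-,hydrophobic,0.4411,2.4353,1.0765,0.5620,3.0480,0.01
PHE,K+,hydrophobic,0.4821,2.5059,1.1294,0.6969,3.7382,0.01
PHE,Cl-,hydrophobic,0.4821,2.5059,1.1294,0.6969,3.7382,0.01
PRO,K+,hydrophobic,0.4758,2.3647,1.0235,0.5918,3.1804,0.01
PRO,Cl-,hydrophobic,0.4758,2.3647,1.0235,0.5918,3.1804,0.01
SER,K+,polar,0.4505,2.2941,0.9706,0.8117,4.3127,0.01
SER,Cl-,polar,0.4505,2.2941,0.9706,0.8117,4.3127,0.01
THR,K+,polar,0.4632,2.3647,1.0235,0.6016,3.2089,0.01
THR,Cl-,polar,0.4632,2.3647,1.0235,0.6016,3.2089,0.01
TRP,K+,hydrophobic,0.4174,2.6000,1.2000,0.6753,3.5813,0.01
TRP,Cl-,hydrophobic,0.4174,2.6000,1.2000,0.6753,3.5813,0.01
TYR,K+,polar,0.4537,2.5294,1.1471,0.7069,3.7342,0.01
TYR,Cl-,polar,0.4537,2.5294,1.1471,0.7069,3.7342,0.01
VAL,K+,hydrophobic,0.4047,2.4118,1.0588,0.6784,3.5751,0.01
VAL,Cl-,hydrophobic,0.4047,2.4118,1.0588,0.6784,3.5751,0.01
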