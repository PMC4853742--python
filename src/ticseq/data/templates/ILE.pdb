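ATOM      1  N   ILE A   1      -0.165   0.234  -1.207  1.00  0.00           N  
ATOM      2  CA  ILE A   1       0.331  -0.467  -0.015  1.00  0.00           C  
ATOM      3  C   ILE A   1      -0.165   0.234   1.222  1.00  0.00           C  
ATOM      4  O   ILE A   1      -0.367   1.424   1.202  1.00  0.00           O  
ATOM      5  CB  ILE A   1       1.860  -0.467  -0.025  1.00  0.00           C  
ATOM      6  CG1 ILE A   1       2.363  -1.179  -1.281  1.00  0.00           C  
ATOM      7  CG2 ILE A   1       2.377  -1.198   1.216  1.00  0.00           C  
ATOM      8  CD1 ILE A   1       3.892  -1.179  -1.291  1.00  0.00           C  
ATOM      9  OXT ILE A   1      -0.382  -0.464   2.348  1.00  0.00           O  
ATOM     10  H   ILE A   1       0.193   1.174  -1.160  1.00  0.00           H  
ATOM     11  H2  ILE A   1       0.271  -0.205  -2.003  1.00  0.00           H  
ATOM     12  HA  ILE A   1      -0.032  -1.496  -0.020  1.00  0.00           H  
ATOM     13  HB  ILE A   1       2.223   0.560  -0.018  1.00  0.00           H  
ATOM     14 HG12 ILE A   1       1.995  -0.659  -2.165  1.00  0.00           H  
ATOM     15 HG13 ILE A   1       2.000  -2.206  -1.287  1.00  0.00           H  
ATOM     16 HG21 ILE A   1       2.014  -2.224   1.211  1.00  0.00           H  
ATOM     17 HG22 ILE A   1       3.467  -1.197   1.210  1.00  0.00           H  
ATOM     18 HG23 ILE A   1       2.020  -0.690   2.112  1.00  0.00           H  
ATOM     19 HD11 ILE A   1       4.252  -1.686  -2.185  1.00  0.00           H  
ATOM     20 HD12 ILE A   1       4.256  -0.151  -1.284  1.00  0.00           H  
ATOM     21 HD13 ILE A   1       4.261  -1.699  -0.407  1.00  0.00           H  
ATOM     22  HXT ILE A   1      -0.700  -0.014   3.143  1.00  0.00           H  
END
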