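ATOM      1  N   LEU A   1      -0.165   0.234  -1.207  1.00  0.00           N  
ATOM      2  CA  LEU A   1       0.330  -0.468  -0.015  1.00  0.00           C  
ATOM      3  C   LEU A   1      -0.165   0.234   1.222  1.00  0.00           C  
ATOM      4  O   LEU A   1      -0.366   1.425   1.203  1.00  0.00           O  
ATOM      5  CB  LEU A   1       1.859  -0.468  -0.024  1.00  0.00           C  
ATOM      6  CG  LEU A   1       2.362  -1.181  -1.281  1.00  0.00           C  
ATOM      7  CD1 LEU A   1       3.892  -1.181  -1.290  1.00  0.00           C  
ATOM      8  CD2 LEU A   1       1.852  -2.622  -1.289  1.00  0.00           C  
ATOM      9  OXT LEU A   1      -0.383  -0.464   2.348  1.00  0.00           O  
ATOM     10  H   LEU A   1       0.193   1.175  -1.160  1.00  0.00           H  
ATOM     11  H2  LEU A   1       0.271  -0.204  -2.004  1.00  0.00           H  
ATOM     12  HA  LEU A   1      -0.033  -1.495  -0.021  1.00  0.00           H  
ATOM     13  HB2 LEU A   1       2.227  -0.988   0.860  1.00  0.00           H  
ATOM     14  HB3 LEU A   1       2.224   0.559  -0.018  1.00  0.00           H  
ATOM     15  HG  LEU A   1       1.995  -0.660  -2.164  1.00  0.00           H  
ATOM     16 HD11 LEU A   1       4.250  -1.689  -2.185  1.00  0.00           H  
ATOM     17 HD12 LEU A   1       4.256  -0.153  -1.284  1.00  0.00           H  
ATOM     18 HD13 LEU A   1       4.260  -1.701  -0.406  1.00  0.00           H  
ATOM     19 HD21 LEU A   1       2.220  -3.142  -0.405  1.00  0.00           H  
ATOM     20 HD22 LEU A   1       0.762  -2.622  -1.283  1.00  0.00           H  
ATOM     21 HD23 LEU A   1       2.210  -3.130  -2.185  1.00  0.00           H  
ATOM     22  HXT LEU A   1      -0.700  -0.015   3.142  1.00  0.00           H  
END
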