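ATOM      1  N   MET A   1      -0.165   0.234  -1.207  1.00  0.00           N  
ATOM      2  CA  MET A   1       0.331  -0.468  -0.015  1.00  0.00           C  
ATOM      3  C   MET A   1      -0.165   0.234   1.222  1.00  0.00           C  
ATOM      4  O   MET A   1      -0.367   1.424   1.203  1.00  0.00           O  
ATOM      5  CB  MET A   1       1.860  -0.468  -0.025  1.00  0.00           C  
ATOM      6  CG  MET A   1       2.363  -1.179  -1.280  1.00  0.00           C  
ATOM      7  SD  MET A   1       4.177  -1.179  -1.291  1.00  0.00           S  
ATOM      8  CE  MET A   1       4.485  -2.060  -2.845  1.00  0.00           C  
ATOM      9  OXT MET A   1      -0.383  -0.465   2.348  1.00  0.00           O  
ATOM     10  H   MET A   1       0.194   1.175  -1.160  1.00  0.00           H  
ATOM     11  H2  MET A   1       0.273  -0.203  -2.004  1.00  0.00           H  
ATOM     12  HA  MET A   1      -0.032  -1.495  -0.021  1.00  0.00           H  
ATOM     13  HB2 MET A   1       2.228  -0.987   0.860  1.00  0.00           H  
ATOM     14  HB3 MET A   1       2.223   0.561  -0.019  1.00  0.00           H  
ATOM     15  HG2 MET A   1       1.996  -0.658  -2.165  1.00  0.00           H  
ATOM     16  HG3 MET A   1       2.000  -2.206  -1.286  1.00  0.00           H  
ATOM     17  HE1 MET A   1       5.558  -2.149  -3.008  1.00  0.00           H  
ATOM     18  HE2 MET A   1       4.043  -3.055  -2.792  1.00  0.00           H  
ATOM     19  HE3 MET A   1       4.038  -1.507  -3.671  1.00  0.00           H  
ATOM     20  HXT MET A   1      -0.701  -0.015   3.142  1.00  0.00           H  
END
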