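ATOM      1  N   VAL A   1      -0.165   0.234  -1.207  1.00  0.00           N  
ATOM      2  CA  VAL A   1       0.330  -0.467  -0.015  1.00  0.00           C  
ATOM      3  C   VAL A   1      -0.165   0.234   1.222  1.00  0.00           C  
ATOM      4  O   VAL A   1      -0.367   1.424   1.202  1.00  0.00           O  
ATOM      5  CB  VAL A   1       1.859  -0.467  -0.024  1.00  0.00           C  
ATOM      6  CG1 VAL A   1       2.363  -1.179  -1.281  1.00  0.00           C  
ATOM      7  CG2 VAL A   1       2.369   0.974  -0.015  1.00  0.00           C  
ATOM      8  OXT VAL A   1      -0.384  -0.465   2.347  1.00  0.00           O  
ATOM      9  H   VAL A   1       0.194   1.175  -1.159  1.00  0.00           H  
ATOM     10  H2  VAL A   1       0.273  -0.204  -2.004  1.00  0.00           H  
ATOM     11  HA  VAL A   1      -0.033  -1.495  -0.021  1.00  0.00           H  
ATOM     12  HB  VAL A   1       2.227  -0.989   0.861  1.00  0.00           H  
ATOM     13 HG11 VAL A   1       3.453  -1.180  -1.287  1.00  0.00           H  
ATOM     14 HG12 VAL A   1       2.000  -2.206  -1.286  1.00  0.00           H  
ATOM     15 HG13 VAL A   1       1.996  -0.659  -2.164  1.00  0.00           H  
ATOM     16 HG21 VAL A   1       2.002   1.495  -0.899  1.00  0.00           H  
ATOM     17 HG22 VAL A   1       2.011   1.481   0.880  1.00  0.00           H  
ATOM     18 HG23 VAL A   1       3.460   0.975  -0.020  1.00  0.00           H  
ATOM     19  HXT VAL A   1      -0.702  -0.014   3.142  1.00  0.00           H  
END
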