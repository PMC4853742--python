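ATOM      1  N   SER A   1      -0.165   0.234  -1.207  1.00  0.00           N  
ATOM      2  CA  SER A   1       0.331  -0.468  -0.015  1.00  0.00           C  
ATOM      3  C   SER A   1      -0.165   0.234   1.222  1.00  0.00           C  
ATOM      4  O   SER A   1      -0.367   1.424   1.203  1.00  0.00           O  
ATOM      5  CB  SER A   1       1.860  -0.468  -0.024  1.00  0.00           C  
ATOM      6  OG  SER A   1       2.330  -1.131  -1.198  1.00  0.00           O  
ATOM      7  OXT SER A   1      -0.383  -0.465   2.347  1.00  0.00           O  
ATOM      8  H   SER A   1       0.193   1.175  -1.160  1.00  0.00           H  
ATOM      9  H2  SER A   1       0.273  -0.203  -2.004  1.00  0.00           H  
ATOM     10  HA  SER A   1      -0.033  -1.495  -0.022  1.00  0.00           H  
ATOM     11  HB2 SER A   1       2.222   0.560  -0.018  1.00  0.00           H  
ATOM     12  HB3 SER A   1       2.228  -0.988   0.860  1.00  0.00           H  
ATOM     13  HG  SER A   1       3.296  -1.109  -1.163  1.00  0.00           H  
ATOM     14  HXT SER A   1      -0.702  -0.016   3.142  1.00  0.00           H  
END
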