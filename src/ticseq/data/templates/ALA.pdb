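ATOM      1  N   ALA A   1      -0.165   0.233  -1.207  1.00  0.00           N  
ATOM      2  CA  ALA A   1       0.330  -0.467  -0.015  1.00  0.00           C  
ATOM      3  C   ALA A   1      -0.165   0.233   1.222  1.00  0.00           C  
ATOM      4  O   ALA A   1      -0.368   1.423   1.202  1.00  0.00           O  
ATOM      5  CB  ALA A   1       1.859  -0.467  -0.023  1.00  0.00           C  
ATOM      6  OXT ALA A   1      -0.383  -0.465   2.347  1.00  0.00           O  
ATOM      7  H   ALA A   1       0.193   1.175  -1.160  1.00  0.00           H  
ATOM      8  H2  ALA A   1       0.273  -0.204  -2.004  1.00  0.00           H  
ATOM      9  HA  ALA A   1      -0.032  -1.495  -0.022  1.00  0.00           H  
ATOM     10  HB1 ALA A   1       2.219  -0.974  -0.919  1.00  0.00           H  
ATOM     11  HB2 ALA A   1       2.222   0.561  -0.018  1.00  0.00           H  
ATOM     12  HB3 ALA A   1       2.228  -0.987   0.861  1.00  0.00           H  
ATOM     13  HXT ALA A   1      -0.702  -0.016   3.142  1.00  0.00           H  
END
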