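ATOM      1  N   THR A   1      -0.165   0.234  -1.207  1.00  0.00           N  
ATOM      2  CA  THR A   1       0.331  -0.468  -0.015  1.00  0.00           C  
ATOM      3  C   THR A   1      -0.165   0.234   1.222  1.00  0.00           C  
ATOM      4  O   THR A   1      -0.366   1.424   1.203  1.00  0.00           O  
ATOM      5  CB  THR A   1       1.860  -0.468  -0.025  1.00  0.00           C  
ATOM      6  OG1 THR A   1       2.336   0.878  -0.017  1.00  0.00           O  
ATOM      7  CG2 THR A   1       2.363  -1.180  -1.282  1.00  0.00           C  
ATOM      8  OXT THR A   1      -0.383  -0.465   2.347  1.00  0.00           O  
ATOM      9  H   THR A   1       0.194   1.174  -1.160  1.00  0.00           H  
ATOM     10  H2  THR A   1       0.272  -0.204  -2.005  1.00  0.00           H  
ATOM     11  HA  THR A   1      -0.034  -1.495  -0.022  1.00  0.00           H  
ATOM     12  HB  THR A   1       2.228  -0.989   0.859  1.00  0.00           H  
ATOM     13  HG1 THR A   1       1.989   1.302  -0.813  1.00  0.00           H  
ATOM     14 HG21 THR A   1       3.452  -1.180  -1.287  1.00  0.00           H  
ATOM     15 HG22 THR A   1       1.999  -2.207  -1.288  1.00  0.00           H  
ATOM     16 HG23 THR A   1       1.996  -0.660  -2.165  1.00  0.00           H  
ATOM     17  HXT THR A   1      -0.700  -0.015   3.141  1.00  0.00           H  
END
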