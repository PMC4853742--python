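ATOM      1  N   CYS A   1      -0.166   0.234  -1.206  1.00  0.00           N  
ATOM      2  CA  CYS A   1       0.331  -0.468  -0.015  1.00  0.00           C  
ATOM      3  C   CYS A   1      -0.166   0.234   1.222  1.00  0.00           C  
ATOM      4  O   CYS A   1      -0.367   1.423   1.202  1.00  0.00           O  
ATOM      5  CB  CYS A   1       1.859  -0.468  -0.023  1.00  0.00           C  
ATOM      6  SG  CYS A   1       2.457  -1.311  -1.514  1.00  0.00           S  
ATOM      7  OXT CYS A   1      -0.384  -0.465   2.347  1.00  0.00           O  
ATOM      8  H   CYS A   1       0.194   1.175  -1.160  1.00  0.00           H  
ATOM      9  H2  CYS A   1       0.273  -0.203  -2.004  1.00  0.00           H  
ATOM     10  HA  CYS A   1      -0.033  -1.495  -0.022  1.00  0.00           H  
ATOM     11  HB2 CYS A   1       2.223   0.560  -0.018  1.00  0.00           H  
ATOM     12  HB3 CYS A   1       2.227  -0.988   0.861  1.00  0.00           H  
ATOM     13  HG  CYS A   1       3.784  -1.203  -1.329  1.00  0.00           H  
ATOM     14  HXT CYS A   1      -0.702  -0.015   3.141  1.00  0.00           H  
END
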