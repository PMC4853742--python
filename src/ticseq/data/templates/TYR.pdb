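ATOM      1  N   TYR A   1      -0.165   0.234  -1.207  1.00  0.00           N  
ATOM      2  CA  TYR A   1       0.331  -0.467  -0.016  1.00  0.00           C  
ATOM      3  C   TYR A   1      -0.165   0.234   1.223  1.00  0.00           C  
ATOM      4  O   TYR A   1      -0.368   1.423   1.203  1.00  0.00           O  
ATOM      5  CB  TYR A   1       1.860  -0.467  -0.024  1.00  0.00           C  
ATOM      6  CG  TYR A   1       2.355  -1.168  -1.262  1.00  0.00           C  
ATOM      7  CD1 TYR A   1       2.580  -0.447  -2.420  1.00  0.00           C  
ATOM      8  CD2 TYR A   1       2.591  -2.530  -1.236  1.00  0.00           C  
ATOM      9  CE1 TYR A   1       3.034  -1.087  -3.556  1.00  0.00           C  
ATOM     10  CE2 TYR A   1       3.041  -3.175  -2.371  1.00  0.00           C  
ATOM     11  CZ  TYR A   1       3.267  -2.454  -3.536  1.00  0.00           C  
ATOM     12  OH  TYR A   1       3.714  -3.086  -4.651  1.00  0.00           O  
ATOM     13  OXT TYR A   1      -0.383  -0.466   2.347  1.00  0.00           O  
ATOM     14  H   TYR A   1       0.194   1.176  -1.159  1.00  0.00           H  
ATOM     15  H2  TYR A   1       0.273  -0.204  -2.004  1.00  0.00           H  
ATOM     16  HA  TYR A   1      -0.033  -1.496  -0.022  1.00  0.00           H  
ATOM     17  HB2 TYR A   1       2.223   0.559  -0.017  1.00  0.00           H  
ATOM     18  HB3 TYR A   1       2.228  -0.989   0.860  1.00  0.00           H  
ATOM     19  HD1 TYR A   1       2.400   0.617  -2.435  1.00  0.00           H  
ATOM     20  HD2 TYR A   1       2.417  -3.091  -0.331  1.00  0.00           H  
ATOM     21  HE1 TYR A   1       3.208  -0.524  -4.461  1.00  0.00           H  
ATOM     22  HE2 TYR A   1       3.221  -4.240  -2.353  1.00  0.00           H  
ATOM     23  HH  TYR A   1       4.680  -3.064  -4.618  1.00  0.00           H  
ATOM     24  HXT TYR A   1      -0.703  -0.016   3.142  1.00  0.00           H  
END
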