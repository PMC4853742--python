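ATOM      1  N   PHE A   1      -0.166   0.233  -1.207  1.00  0.00           N  
ATOM      2  CA  PHE A   1       0.331  -0.467  -0.016  1.00  0.00           C  
ATOM      3  C   PHE A   1      -0.166   0.233   1.223  1.00  0.00           C  
ATOM      4  O   PHE A   1      -0.367   1.423   1.203  1.00  0.00           O  
ATOM      5  CB  PHE A   1       1.860  -0.467  -0.025  1.00  0.00           C  
ATOM      6  CG  PHE A   1       2.356  -1.166  -1.262  1.00  0.00           C  
ATOM      7  CD1 PHE A   1       2.579  -0.448  -2.421  1.00  0.00           C  
ATOM      8  CD2 PHE A   1       2.592  -2.529  -1.238  1.00  0.00           C  
ATOM      9  CE1 PHE A   1       3.034  -1.091  -3.556  1.00  0.00           C  
ATOM     10  CE2 PHE A   1       3.044  -3.171  -2.375  1.00  0.00           C  
ATOM     11  CZ  PHE A   1       3.267  -2.451  -3.534  1.00  0.00           C  
ATOM     12  OXT PHE A   1      -0.382  -0.465   2.348  1.00  0.00           O  
ATOM     13  H   PHE A   1       0.193   1.175  -1.159  1.00  0.00           H  
ATOM     14  H2  PHE A   1       0.272  -0.204  -2.003  1.00  0.00           H  
ATOM     15  HA  PHE A   1      -0.032  -1.494  -0.022  1.00  0.00           H  
ATOM     16  HB2 PHE A   1       2.223   0.561  -0.018  1.00  0.00           H  
ATOM     17  HB3 PHE A   1       2.229  -0.987   0.859  1.00  0.00           H  
ATOM     18  HD1 PHE A   1       2.399   0.617  -2.438  1.00  0.00           H  
ATOM     19  HD2 PHE A   1       2.419  -3.091  -0.332  1.00  0.00           H  
ATOM     20  HE1 PHE A   1       3.208  -0.528  -4.462  1.00  0.00           H  
ATOM     21  HE2 PHE A   1       3.224  -4.237  -2.357  1.00  0.00           H  
ATOM     22  HZ  PHE A   1       3.622  -2.954  -4.422  1.00  0.00           H  
ATOM     23  HXT PHE A   1      -0.701  -0.016   3.142  1.00  0.00           H  
END
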