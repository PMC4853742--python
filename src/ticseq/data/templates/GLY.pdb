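ATOM      1  N   GLY A   1      -0.165  -0.234  -1.207  1.00  0.00           N  
ATOM      2  CA  GLY A   1       0.331   0.468  -0.015  1.00  0.00           C  
ATOM      3  C   GLY A   1      -0.165  -0.234   1.223  1.00  0.00           C  
ATOM      4  O   GLY A   1      -0.860  -1.217   1.123  1.00  0.00           O  
ATOM      5  OXT GLY A   1       0.165   0.234   2.437  1.00  0.00           O  
ATOM      6  H   GLY A   1      -1.171  -0.304  -1.193  1.00  0.00           H  
ATOM      7  H2  GLY A   1       0.154   0.218  -2.051  1.00  0.00           H  
ATOM      8  HA2 GLY A   1       1.420   0.468  -0.021  1.00  0.00           H  
ATOM      9  HA3 GLY A   1      -0.033   1.495  -0.021  1.00  0.00           H  
ATOM     10  HXT GLY A   1      -0.177  -0.249   3.202  1.00  0.00           H  
END
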