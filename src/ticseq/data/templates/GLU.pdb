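ATOM      1  N   GLU A   1      -0.165   0.234  -1.207  1.00  0.00           N  
ATOM      2  CA  GLU A   1       0.330  -0.468  -0.016  1.00  0.00           C  
ATOM      3  C   GLU A   1      -0.165   0.234   1.223  1.00  0.00           C  
ATOM      4  O   GLU A   1      -0.538   1.381   1.159  1.00  0.00           O  
ATOM      5  CB  GLU A   1       1.861  -0.468  -0.023  1.00  0.00           C  
ATOM      6  CG  GLU A   1       2.363  -1.287  -1.215  1.00  0.00           C  
ATOM      7  CD  GLU A   1       3.871  -1.287  -1.223  1.00  0.00           C  
ATOM      8  OE1 GLU A   1       4.480  -0.693  -0.364  1.00  0.00           O  
ATOM      9  OE2 GLU A   1       4.537  -1.947  -2.184  1.00  0.00           O  
ATOM     10  OXT GLU A   1      -0.192  -0.416   2.397  1.00  0.00           O  
ATOM     11  H   GLU A   1       0.158   1.190  -1.226  1.00  0.00           H  
ATOM     12  H2  GLU A   1       0.099  -0.253  -2.050  1.00  0.00           H  
ATOM     13  HA  GLU A   1      -0.033  -1.495  -0.021  1.00  0.00           H  
ATOM     14  HB2 GLU A   1       2.224   0.556  -0.108  1.00  0.00           H  
ATOM     15  HB3 GLU A   1       2.229  -0.909   0.902  1.00  0.00           H  
ATOM     16  HG2 GLU A   1       2.000  -2.311  -1.131  1.00  0.00           H  
ATOM     17  HG3 GLU A   1       1.995  -0.844  -2.140  1.00  0.00           H  
ATOM     18  HE2 GLU A   1       5.502  -1.918  -2.147  1.00  0.00           H  
ATOM     19  HXT GLU A   1      -0.518   0.075   3.163  1.00  0.00           H  
END
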