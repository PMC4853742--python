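ATOM      1  N   ASP A   1      -0.165   0.234  -1.207  1.00  0.00           N  
ATOM      2  CA  ASP A   1       0.331  -0.467  -0.016  1.00  0.00           C  
ATOM      3  C   ASP A   1      -0.165   0.234   1.223  1.00  0.00           C  
ATOM      4  O   ASP A   1      -0.538   1.382   1.159  1.00  0.00           O  
ATOM      5  CB  ASP A   1       1.861  -0.467  -0.023  1.00  0.00           C  
ATOM      6  CG  ASP A   1       2.357  -1.274  -1.196  1.00  0.00           C  
ATOM      7  OD1 ASP A   1       1.567  -1.795  -1.947  1.00  0.00           O  
ATOM      8  OD2 ASP A   1       3.675  -1.413  -1.405  1.00  0.00           O  
ATOM      9  OXT ASP A   1      -0.192  -0.416   2.397  1.00  0.00           O  
ATOM     10  H   ASP A   1      -1.172   0.191  -1.258  1.00  0.00           H  
ATOM     11  H2  ASP A   1       0.158   1.189  -1.225  1.00  0.00           H  
ATOM     12  HA  ASP A   1      -0.033  -1.495  -0.020  1.00  0.00           H  
ATOM     13  HB2 ASP A   1       2.224   0.557  -0.108  1.00  0.00           H  
ATOM     14  HB3 ASP A   1       2.229  -0.908   0.903  1.00  0.00           H  
ATOM     15  HD2 ASP A   1       3.945  -1.939  -2.170  1.00  0.00           H  
ATOM     16  HXT ASP A   1      -0.518   0.076   3.164  1.00  0.00           H  
END
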