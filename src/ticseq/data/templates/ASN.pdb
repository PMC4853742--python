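ATOM      1  N   ASN A   1      -0.165   0.234  -1.207  1.00  0.00           N  
ATOM      2  CA  ASN A   1       0.330  -0.467  -0.016  1.00  0.00           C  
ATOM      3  C   ASN A   1      -0.165   0.234   1.223  1.00  0.00           C  
ATOM      4  O   ASN A   1      -0.538   1.381   1.159  1.00  0.00           O  
ATOM      5  CB  ASN A   1       1.861  -0.467  -0.024  1.00  0.00           C  
ATOM      6  CG  ASN A   1       2.357  -1.272  -1.197  1.00  0.00           C  
ATOM      7  OD1 ASN A   1       1.565  -1.796  -1.952  1.00  0.00           O  
ATOM      8  ND2 ASN A   1       3.681  -1.412  -1.407  1.00  0.00           N  
ATOM      9  OXT ASN A   1      -0.192  -0.417   2.397  1.00  0.00           O  
ATOM     10  H   ASN A   1      -1.172   0.192  -1.259  1.00  0.00           H  
ATOM     11  H2  ASN A   1       0.158   1.189  -1.225  1.00  0.00           H  
ATOM     12  HA  ASN A   1      -0.032  -1.495  -0.022  1.00  0.00           H  
ATOM     13  HB2 ASN A   1       2.223   0.558  -0.108  1.00  0.00           H  
ATOM     14  HB3 ASN A   1       2.229  -0.908   0.902  1.00  0.00           H  
ATOM     15 HD21 ASN A   1       4.315  -0.994  -0.803  1.00  0.00           H  
ATOM     16 HD22 ASN A   1       4.001  -1.930  -2.161  1.00  0.00           H  
ATOM     17  HXT ASN A   1      -0.518   0.074   3.164  1.00  0.00           H  
END
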