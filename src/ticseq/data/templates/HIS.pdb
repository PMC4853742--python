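ATOM      1  N   HIS A   1      -0.173   0.219  -1.206  1.00  0.00           N  
ATOM      2  CA  HIS A   1       0.346  -0.437  -0.033  1.00  0.00           C  
ATOM      3  C   HIS A   1      -0.173   0.219   1.239  1.00  0.00           C  
ATOM      4  O   HIS A   1      -0.384   1.424   1.330  1.00  0.00           O  
ATOM      5  CB  HIS A   1       1.880  -0.437  -0.032  1.00  0.00           C  
ATOM      6  CG  HIS A   1       2.469  -1.518   0.842  1.00  0.00           C  
ATOM      7  ND1 HIS A   1       2.735  -1.273   2.144  1.00  0.00           N  
ATOM      8  CD2 HIS A   1       2.802  -2.779   0.543  1.00  0.00           C  
ATOM      9  CE1 HIS A   1       3.243  -2.389   2.676  1.00  0.00           C  
ATOM     10  NE2 HIS A   1       3.288  -3.313   1.711  1.00  0.00           N  
ATOM     11  OXT HIS A   1      -0.397  -0.633   2.269  1.00  0.00           O  
ATOM     12  H   HIS A   1      -1.016  -0.133  -1.629  1.00  0.00           H  
ATOM     13  H2  HIS A   1       0.410   0.876  -1.697  1.00  0.00           H  
ATOM     14  HA  HIS A   1      -0.053  -1.458  -0.050  1.00  0.00           H  
ATOM     15  HB2 HIS A   1       2.263  -0.578  -1.052  1.00  0.00           H  
ATOM     16  HB3 HIS A   1       2.259   0.543   0.285  1.00  0.00           H  
ATOM     17  HD1 HIS A   1       2.584  -0.403   2.647  1.00  0.00           H  
ATOM     18  HD2 HIS A   1       2.777  -3.414  -0.320  1.00  0.00           H  
ATOM     19  HE1 HIS A   1       3.558  -2.520   3.699  1.00  0.00           H  
ATOM     20  HE2 HIS A   1       3.628  -4.263   1.828  1.00  0.00           H  
ATOM     21  HXT HIS A   1      -0.737  -0.211   3.085  1.00  0.00           H  
END
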