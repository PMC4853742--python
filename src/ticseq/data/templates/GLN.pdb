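ATOM      1  N   GLN A   1      -0.165   0.234  -1.207  1.00  0.00           N  
ATOM      2  CA  GLN A   1       0.331  -0.467  -0.015  1.00  0.00           C  
ATOM      3  C   GLN A   1      -0.165   0.234   1.222  1.00  0.00           C  
ATOM      4  O   GLN A   1      -0.368   1.424   1.202  1.00  0.00           O  
ATOM      5  CB  GLN A   1       1.860  -0.467  -0.024  1.00  0.00           C  
ATOM      6  CG  GLN A   1       2.363  -1.177  -1.281  1.00  0.00           C  
ATOM      7  CD  GLN A   1       3.870  -1.177  -1.290  1.00  0.00           C  
ATOM      8  OE1 GLN A   1       4.480  -0.659  -0.380  1.00  0.00           O  
ATOM      9  NE2 GLN A   1       4.539  -1.752  -2.308  1.00  0.00           N  
ATOM     10  OXT GLN A   1      -0.382  -0.466   2.348  1.00  0.00           O  
ATOM     11  H   GLN A   1       0.192   1.175  -1.160  1.00  0.00           H  
ATOM     12  H2  GLN A   1       0.272  -0.202  -2.004  1.00  0.00           H  
ATOM     13  HA  GLN A   1      -0.031  -1.495  -0.022  1.00  0.00           H  
ATOM     14  HB2 GLN A   1       2.222   0.561  -0.018  1.00  0.00           H  
ATOM     15  HB3 GLN A   1       2.228  -0.987   0.860  1.00  0.00           H  
ATOM     16  HG2 GLN A   1       2.001  -2.206  -1.287  1.00  0.00           H  
ATOM     17  HG3 GLN A   1       1.995  -0.657  -2.165  1.00  0.00           H  
ATOM     18 HE21 GLN A   1       5.508  -1.752  -2.315  1.00  0.00           H  
ATOM     19 HE22 GLN A   1       4.050  -2.166  -3.037  1.00  0.00           H  
ATOM     20  HXT GLN A   1      -0.701  -0.016   3.143  1.00  0.00           H  
END
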