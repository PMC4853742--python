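ATOM      1  N   LYS A   1      -0.165   0.234  -1.207  1.00  0.00           N  
ATOM      2  CA  LYS A   1       0.330  -0.468  -0.015  1.00  0.00           C  
ATOM      3  C   LYS A   1      -0.165   0.234   1.223  1.00  0.00           C  
ATOM      4  O   LYS A   1      -0.537   1.381   1.159  1.00  0.00           O  
ATOM      5  CB  LYS A   1       1.860  -0.468  -0.023  1.00  0.00           C  
ATOM      6  CG  LYS A   1       2.363  -1.287  -1.214  1.00  0.00           C  
ATOM      7  CD  LYS A   1       3.894  -1.288  -1.222  1.00  0.00           C  
ATOM      8  CE  LYS A   1       4.397  -2.107  -2.412  1.00  0.00           C  
ATOM      9  NZ  LYS A   1       5.866  -2.108  -2.420  1.00  0.00           N  
ATOM     10  OXT LYS A   1      -0.192  -0.416   2.397  1.00  0.00           O  
ATOM     11  H   LYS A   1       0.195   1.175  -1.160  1.00  0.00           H  
ATOM     12  H2  LYS A   1       0.272  -0.203  -2.004  1.00  0.00           H  
ATOM     13  HA  LYS A   1      -0.034  -1.495  -0.021  1.00  0.00           H  
ATOM     14  HB2 LYS A   1       2.224   0.556  -0.107  1.00  0.00           H  
ATOM     15  HB3 LYS A   1       2.229  -0.910   0.903  1.00  0.00           H  
ATOM     16  HG2 LYS A   1       2.000  -2.311  -1.129  1.00  0.00           H  
ATOM     17  HG3 LYS A   1       1.995  -0.846  -2.140  1.00  0.00           H  
ATOM     18  HD2 LYS A   1       4.258  -0.264  -1.306  1.00  0.00           H  
ATOM     19  HD3 LYS A   1       4.261  -1.729  -0.296  1.00  0.00           H  
ATOM     20  HE2 LYS A   1       4.034  -3.131  -2.329  1.00  0.00           H  
ATOM     21  HE3 LYS A   1       4.029  -1.666  -3.338  1.00  0.00           H  
ATOM     22  HZ1 LYS A   1       6.202  -1.160  -2.498  1.00  0.00           H  
ATOM     23  HZ2 LYS A   1       6.206  -2.516  -1.563  1.00  0.00           H  
ATOM     24  HZ3 LYS A   1       6.198  -2.648  -3.205  1.00  0.00           H  
ATOM     25  HXT LYS A   1      -0.511   0.034   3.192  1.00  0.00           H  
END
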