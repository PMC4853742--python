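ATOM      1  N   ARG A   1      -0.184   0.226  -1.195  1.00  0.00           N  
ATOM      2  CA  ARG A   1       0.368  -0.452  -0.023  1.00  0.00           C  
ATOM      3  C   ARG A   1      -0.184   0.226   1.218  1.00  0.00           C  
ATOM      4  O   ARG A   1      -0.903   1.216   1.227  1.00  0.00           O  
ATOM      5  CB  ARG A   1       1.904  -0.452  -0.043  1.00  0.00           C  
ATOM      6  CG  ARG A   1       2.544   0.944   0.038  1.00  0.00           C  
ATOM      7  CD  ARG A   1       4.069   0.884   0.073  1.00  0.00           C  
ATOM      8  NE  ARG A   1       4.590   0.250  -1.114  1.00  0.00           N  
ATOM      9  CZ  ARG A   1       5.964   0.064  -1.343  1.00  0.00           C  
ATOM     10  NH1 ARG A   1       6.420  -0.553  -2.503  1.00  0.00           N  
ATOM     11  NH2 ARG A   1       6.888   0.501  -0.399  1.00  0.00           N  
ATOM     12  OXT ARG A   1       0.213  -0.401   2.358  1.00  0.00           O  
ATOM     13  H   ARG A   1      -0.024  -0.183  -2.090  1.00  0.00           H  
ATOM     14  H2  ARG A   1      -0.516   1.158  -1.083  1.00  0.00           H  
ATOM     15  HA  ARG A   1       0.001  -1.485  -0.035  1.00  0.00           H  
ATOM     16  HB2 ARG A   1       2.248  -0.951  -0.958  1.00  0.00           H  
ATOM     17  HB3 ARG A   1       2.270  -1.060   0.795  1.00  0.00           H  
ATOM     18  HG2 ARG A   1       2.203   1.451   0.949  1.00  0.00           H  
ATOM     19  HG3 ARG A   1       2.220   1.556  -0.812  1.00  0.00           H  
ATOM     20  HD2 ARG A   1       4.473   1.901   0.131  1.00  0.00           H  
ATOM     21  HD3 ARG A   1       4.414   0.343   0.961  1.00  0.00           H  
ATOM     22  HE  ARG A   1       3.953  -0.089  -1.845  1.00  0.00           H  
ATOM     23 HH11 ARG A   1       7.416  -0.687  -2.667  1.00  0.00           H  
ATOM     24 HH12 ARG A   1       5.783  -0.885  -3.222  1.00  0.00           H  
ATOM     25 HH21 ARG A   1       6.589   0.955   0.460  1.00  0.00           H  
ATOM     26 HH22 ARG A   1       7.888   0.375  -0.543  1.00  0.00           H  
ATOM     27  HXT ARG A   1      -0.119  -0.004   3.192  1.00  0.00           H  
END
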