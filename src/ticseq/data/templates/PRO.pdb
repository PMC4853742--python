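ATOM      1  N   PRO A   1      -0.151   0.242  -1.225  1.00  0.00           N  
ATOM      2  CA  PRO A   1       0.301  -0.483  -0.009  1.00  0.00           C  
ATOM      3  C   PRO A   1      -0.151   0.242   1.233  1.00  0.00           C  
ATOM      4  O   PRO A   1      -0.508   1.394   1.164  1.00  0.00           O  
ATOM      5  CB  PRO A   1       1.842  -0.483  -0.102  1.00  0.00           C  
ATOM      6  CG  PRO A   1       2.153  -0.315  -1.603  1.00  0.00           C  
ATOM      7  CD  PRO A   1       0.773  -0.226  -2.291  1.00  0.00           C  
ATOM      8  OXT PRO A   1      -0.154  -0.392   2.416  1.00  0.00           O  
ATOM      9  H   PRO A   1      -1.065  -0.115  -1.456  1.00  0.00           H  
ATOM     10  HA  PRO A   1      -0.080  -1.504  -0.012  1.00  0.00           H  
ATOM     11  HB2 PRO A   1       2.256   0.351   0.465  1.00  0.00           H  
ATOM     12  HB3 PRO A   1       2.244  -1.428   0.264  1.00  0.00           H  
ATOM     13  HG2 PRO A   1       2.718   0.601  -1.773  1.00  0.00           H  
ATOM     14  HG3 PRO A   1       2.706  -1.177  -1.975  1.00  0.00           H  
ATOM     15  HD2 PRO A   1       0.802   0.491  -3.112  1.00  0.00           H  
ATOM     16  HD3 PRO A   1       0.466  -1.207  -2.653  1.00  0.00           H  
ATOM     17  HXT PRO A   1      -0.444   0.073   3.213  1.00  0.00           H  
END
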