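ATOM      1  N   TRP A   1      -0.166   0.234  -1.207  1.00  0.00           N  
ATOM      2  CA  TRP A   1       0.331  -0.468  -0.016  1.00  0.00           C  
ATOM      3  C   TRP A   1      -0.166   0.234   1.223  1.00  0.00           C  
ATOM      4  O   TRP A   1      -0.368   1.424   1.202  1.00  0.00           O  
ATOM      5  CB  TRP A   1       1.860  -0.468  -0.023  1.00  0.00           C  
ATOM      6  CG  TRP A   1       2.355  -1.169  -1.262  1.00  0.00           C  
ATOM      7  CD1 TRP A   1       2.616  -0.601  -2.450  1.00  0.00           C  
ATOM      8  CD2 TRP A   1       2.651  -2.596  -1.395  1.00  0.00           C  
ATOM      9  NE1 TRP A   1       3.049  -1.551  -3.336  1.00  0.00           N  
ATOM     10  CE2 TRP A   1       3.080  -2.783  -2.722  1.00  0.00           C  
ATOM     11  CE3 TRP A   1       2.574  -3.688  -0.529  1.00  0.00           C  
ATOM     12  CZ2 TRP A   1       3.432  -4.058  -3.151  1.00  0.00           C  
ATOM     13  CZ3 TRP A   1       2.926  -4.932  -0.972  1.00  0.00           C  
ATOM     14  CH2 TRP A   1       3.354  -5.120  -2.278  1.00  0.00           C  
ATOM     15  OXT TRP A   1      -0.382  -0.465   2.348  1.00  0.00           O  
ATOM     16  H   TRP A   1       0.194   1.176  -1.159  1.00  0.00           H  
ATOM     17  H2  TRP A   1       0.272  -0.204  -2.005  1.00  0.00           H  
ATOM     18  HA  TRP A   1      -0.032  -1.495  -0.021  1.00  0.00           H  
ATOM     19  HB2 TRP A   1       2.223   0.560  -0.018  1.00  0.00           H  
ATOM     20  HB3 TRP A   1       2.228  -0.988   0.860  1.00  0.00           H  
ATOM     21  HD1 TRP A   1       2.501   0.448  -2.675  1.00  0.00           H  
ATOM     22  HE1 TRP A   1       3.298  -1.381  -4.257  1.00  0.00           H  
ATOM     23  HE3 TRP A   1       2.242  -3.549   0.489  1.00  0.00           H  
ATOM     24  HZ2 TRP A   1       3.765  -4.215  -4.167  1.00  0.00           H  
ATOM     25  HZ3 TRP A   1       2.871  -5.775  -0.300  1.00  0.00           H  
ATOM     26  HH2 TRP A   1       3.628  -6.109  -2.615  1.00  0.00           H  
ATOM     27  HXT TRP A   1      -0.702  -0.015   3.142  1.00  0.00           H  
END
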