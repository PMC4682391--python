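H GUYH850105
D Apparent partition energies calculated from Chothia index (Guy, 1985)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   -0.27    2.00    0.61    0.50   -0.23    1.00    0.33   -0.22    0.37   -0.80
   -0.44    1.17   -0.31   -0.55    0.36    0.17    0.18    0.05    0.48   -0.65
//
H SNEP660104
D Principal component IV (Sneath, 1966)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
  -0.062  -0.167   0.166  -0.079   0.380  -0.025  -0.184  -0.017   0.056  -0.309
  -0.264  -0.371   0.077   0.074  -0.036   0.470   0.348   0.050   0.220  -0.212
//
H CHOP780101
D Normalized frequency of beta-turn (Chou-Fasman, 1978)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.66    0.95    1.56    1.46    1.19    0.98    0.74    1.56    0.95    0.47
    0.59    1.01    0.60    0.60    1.52    1.43    0.96    0.96    1.14    0.50
//
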