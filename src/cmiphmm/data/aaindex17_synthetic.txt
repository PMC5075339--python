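H ANDN920101
D alpha-CH chemical shifts (synthetic stand-in values)
R synthetic
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    4.39    4.66    4.38    4.04    4.68    4.72    4.72    3.98    4.77    4.19
    4.09    4.77    4.02    4.55    4.37    3.97    4.49    4.24    4.22    4.75
//
H ARGP820101
D hydrophobicity index (synthetic stand-in values)
R synthetic
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.98    2.84    2.15    2.61    1.92    1.06    1.98    2.76    1.18    1.30
    2.82    1.84    1.05    0.07    1.44    2.95    2.25    0.00    0.72    1.68
//
H BEGF750101
D conformational parameter of inner helix (synthetic stand-in values)
R synthetic
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.86    0.73    1.32    0.98    0.54    0.99    1.24    0.75    1.02    0.90
    1.52    0.96    0.66    1.10    1.46    0.74    0.53    0.93    0.76    0.76
//
H BUNA790103
D spin-spin coupling constants 3JHalpha-NH (synthetic stand-in values)
R synthetic
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     6.9     7.4     6.8     6.8     8.5     7.9     8.3     5.8     5.6     8.2
     6.3     5.1     7.4     8.0     7.5     5.2     6.5     6.3     5.8     6.6
//
H BHAR880101
D average flexibility indices (synthetic stand-in values)
R synthetic
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.315   0.414   0.465   0.287   0.477   0.376   0.436   0.271   0.367   0.516
   0.411   0.310   0.388   0.507   0.271   0.451   0.493   0.309   0.493   0.310
//
H BURA740102
D normalized frequency of extended structure (synthetic stand-in values)
R synthetic
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.56    1.16    0.54    0.55    1.40    1.64    0.59    0.63    0.73    1.17
    0.71    0.68    0.68    1.21    1.13    1.60    1.13    1.26    1.61    1.54
//
H GEOR030101
D linker propensity from all dataset (synthetic stand-in values)
R synthetic
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.06    0.74    1.29    0.99    1.20    1.37    1.14    0.83    1.36    0.90
    0.87    1.37    1.32    0.92    1.46    1.15    1.14    1.18    0.81    0.83
//
H CHOP780204
D normalized frequency of N-terminal helix (synthetic stand-in values)
R synthetic
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.60    0.60    1.41    1.65    1.65    1.55    0.68    1.56    1.54    1.05
    1.33    0.79    1.38    0.86    0.99    1.77    0.89    1.44    0.95    0.43
//
H CHOP780215
D frequency of the 4th residue in turn (synthetic stand-in values)
R synthetic
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.44    1.40    1.62    1.48    1.56    0.66    0.47    1.00    0.32    1.87
    1.95    1.26    1.52    1.04    0.34    2.01    1.47    1.95    1.37    0.85
//
H JOND920102
D relative mutability (synthetic stand-in values)
R synthetic
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
      58      37      39     103      59      59      57      31     108      50
      67      21      71      53      66      91      55      55      71      76
//
H KHAG800101
D Kerr-constant increments (synthetic stand-in values)
R synthetic
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   15.04    1.38   23.94   20.63    6.46   20.86    4.64   16.30   11.45    3.60
    3.81   12.89   22.79    8.84   18.20   22.22   11.26   18.62    1.87   27.88
//
H FAUJ880104
D STERIMOL length of the side chain (synthetic stand-in values)
R synthetic
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    3.27    3.25    6.44    2.53    4.24    4.19    3.02    6.42    2.04    4.58
    4.47    4.51    2.50    2.37    4.24    2.68    3.05    2.20    5.65    2.75
//
H PALJ810107
D normalized frequency of alpha-helix in all-alpha class (synthetic stand-in values)
R synthetic
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.59    1.57    1.03    0.83    1.07    0.68    0.84    0.70    1.55    0.57
    1.54    1.32    0.60    1.23    1.13    1.34    0.52    0.94    1.42    0.88
//
H RACS820114
D value of theta(i-1) (synthetic stand-in values)
R synthetic
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.36    1.02    0.66    0.61    0.44    0.65    0.44    0.29    0.62    0.40
    0.75    0.20    0.55    0.65    0.41    0.58    0.44    0.92    0.25    0.44
//
H WERD780103
D free energy change of alpha(Ri) to alpha(Rh) (synthetic stand-in values)
R synthetic
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   -0.05   -0.20    0.28    0.03    0.08   -0.22    0.25   -0.02    0.19    0.05
   -0.07   -0.21    0.30    0.28   -0.11    0.08    0.08    0.15   -0.02   -0.30
//
H YUTK870102
D unfolding Gibbs energy in water pH 9.0 (synthetic stand-in values)
R synthetic
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     8.3     8.8     6.5     6.4     9.6     7.8     8.9    10.8     5.4     8.2
     8.8     6.5     5.6     9.8     7.5    11.4    10.0     5.1     7.9     6.9
//
H CHAM830102
D residual from Chou-Fasman beta-sheet correlation (synthetic stand-in values)
R synthetic
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
  -0.279   0.176  -0.266   0.091   0.069  -0.003   0.191  -0.204  -0.046   0.111
  -0.164   0.289   0.271   0.167   0.126  -0.101  -0.008   0.073   0.290   0.243
//
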