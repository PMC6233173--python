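H KYTJ820101
D Hydropathy index (Kyte-Doolittle, 1982)
R PMID:7108955
A Kyte, J. and Doolittle, R.F.
T A simple method for displaying the hydropathic character of a protein
J J. Mol. Biol. 157, 105-132 (1982)
C GIES800101    0.930  JOND750101    0.917
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     1.8    -4.5    -3.5    -3.5     2.5    -3.5    -3.5    -0.4    -3.2     4.5
     3.8    -3.9     1.9     2.8    -1.6    -0.8    -0.7    -0.9    -1.3     4.2
//
H VELV850101
D Electron-ion interaction potential (Veljkovic et al., 1985)
R PMID:2581884
A Veljkovic, V., Cosic, I., Dimitrijevic, B. and Lalovic, D.
T Is it possible to analyze DNA and protein sequences by the methods of
  digital signal processing?
J IEEE Trans. Biomed. Eng. 32, 337-341 (1985)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
  0.0373  0.0959  0.0036  0.1263  0.0829  0.0761  0.0058  0.0050  0.0242  0.0000
  0.0000  0.0371  0.0823  0.0946  0.0198  0.0829  0.0941  0.0548  0.0516  0.0057
//
H FASG760101
D Molecular weight (Fasman, 1976)
R
A Fasman, G.D., ed.
T Handbook of Biochemistry and Molecular Biology, 3rd ed., Proteins - Volume 1
J CRC Press, Cleveland (1976)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   89.09  174.20  132.12  133.10  121.15  146.15  147.13   75.07  155.16  131.17
  131.17  146.19  149.21  165.19  115.13  105.09  119.12  204.23  181.19  117.15
//
H SYNNA00001
D Synthetic fixture record with a missing tryptophan value (not a published index)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     1.0     2.0     3.0     4.0     5.0     6.0     7.0     8.0     9.0    10.0
    11.0    12.0    13.0    14.0    15.0    16.0    17.0      NA    18.0    19.0
//
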