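# Synthetic mock host codon usage table 'mock_balanced' (not a real organism).
# fields: [triplet] [frequency: per thousand] ([number])

AAA 19.6 (   224)  AAC 16.7 (   191)  AAG 16.9 (   194)  AAU 14.1 (   161)
ACA 19.3 (   221)  ACC 13.5 (   154)  ACG 19.7 (   226)  ACU 18.9 (   216)
AGA 13.1 (   150)  AGC 14.0 (   160)  AGG 13.7 (   157)  AGU 13.0 (   149)
AUA 19.9 (   228)  AUC 13.9 (   159)  AUG 17.6 (   201)  AUU 14.6 (   167)
CAA 17.9 (   205)  CAC 15.0 (   172)  CAG 16.8 (   192)  CAU 14.6 (   167)
CCA 15.5 (   177)  CCC 11.3 (   129)  CCG 18.0 (   206)  CCU 13.4 (   153)
CGA 12.6 (   144)  CGC 12.3 (   141)  CGG 15.7 (   180)  CGU 18.6 (   213)
CUA 14.2 (   163)  CUC 11.8 (   135)  CUG 16.9 (   194)  CUU 19.8 (   227)
GAA 16.8 (   192)  GAC 14.6 (   167)  GAG 21.8 (   250)  GAU 16.0 (   183)
GCA 20.4 (   234)  GCC 17.1 (   196)  GCG 21.1 (   241)  GCU 16.7 (   191)
GGA 17.0 (   195)  GGC 12.8 (   146)  GGG 16.4 (   188)  GGU 18.8 (   215)
GUA 19.5 (   223)  GUC 14.7 (   168)  GUG 17.1 (   196)  GUU 15.2 (   174)
UAA  1.1 (    13)  UAC 16.0 (   183)  UAG  1.0 (    11)  UAU 13.5 (   154)
UCA 20.4 (   234)  UCC 18.9 (   216)  UCG 15.8 (   181)  UCU 15.4 (   176)
UGA  1.5 (    17)  UGC 16.2 (   186)  UGG 17.1 (   196)  UGU 13.8 (   158)
UUA 17.1 (   196)  UUC 19.1 (   219)  UUG 18.3 (   209)  UUU 16.1 (   184)
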