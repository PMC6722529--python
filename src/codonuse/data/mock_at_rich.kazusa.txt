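# Synthetic mock host codon usage table 'mock_at_rich' (not a real organism).
# fields: [triplet] [frequency: per thousand] ([number])

AAA 22.3 (   297)  AAC 10.3 (   137)  AAG 12.8 (   171)  AAU 21.5 (   287)
ACA 25.1 (   335)  ACC  8.4 (   112)  ACG  9.5 (   127)  ACU 21.3 (   284)
AGA 19.4 (   259)  AGC  9.4 (   125)  AGG  8.8 (   118)  AGU 27.2 (   363)
AUA 22.5 (   300)  AUC  9.5 (   127)  AUG 12.6 (   168)  AUU 19.7 (   263)
CAA 26.9 (   359)  CAC  7.9 (   106)  CAG 12.1 (   162)  CAU 27.4 (   366)
CCA 26.8 (   357)  CCC  9.5 (   127)  CCG 12.4 (   165)  CCU 22.9 (   305)
CGA 26.4 (   352)  CGC  6.4 (    86)  CGG 13.0 (   174)  CGU 17.5 (   233)
CUA 23.2 (   309)  CUC  6.8 (    91)  CUG  8.8 (   117)  CUU 23.7 (   316)
GAA 23.8 (   318)  GAC  8.2 (   109)  GAG 11.6 (   155)  GAU 28.3 (   377)
GCA 23.9 (   319)  GCC  9.0 (   120)  GCG  9.4 (   125)  GCU 17.7 (   236)
GGA 25.3 (   338)  GGC  8.4 (   112)  GGG 10.3 (   138)  GGU 25.9 (   345)
GUA 17.2 (   230)  GUC  7.6 (   102)  GUG  9.3 (   124)  GUU 23.3 (   311)
UAA  1.0 (    13)  UAC  9.4 (   126)  UAG  1.3 (    17)  UAU 18.5 (   247)
UCA 26.2 (   350)  UCC  8.4 (   112)  UCG  9.7 (   129)  UCU 26.2 (   350)
UGA  0.7 (    10)  UGC  9.7 (   130)  UGG 12.6 (   168)  UGU 19.5 (   260)
UUA 17.4 (   232)  UUC  9.9 (   132)  UUG 13.3 (   177)  UUU 24.7 (   330)
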