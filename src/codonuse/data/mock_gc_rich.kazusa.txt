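# Synthetic mock host codon usage table 'mock_gc_rich' (not a real organism).
# fields: [triplet] [frequency: per thousand] ([number])

AAA  8.6 (   109)  AAC 25.5 (   323)  AAG 19.0 (   241)  AAU 11.4 (   145)
ACA 10.9 (   138)  ACC 26.2 (   332)  ACG 19.8 (   251)  ACU  9.9 (   126)
AGA  9.6 (   122)  AGC 19.9 (   253)  AGG 25.5 (   324)  AGU  9.8 (   124)
AUA 10.9 (   138)  AUC 18.9 (   240)  AUG 24.7 (   313)  AUU 11.8 (   150)
CAA 10.0 (   127)  CAC 22.1 (   280)  CAG 26.2 (   333)  CAU 10.6 (   135)
CCA  8.7 (   110)  CCC 21.6 (   274)  CCG 19.0 (   241)  CCU 11.0 (   140)
CGA  7.2 (    91)  CGC 21.4 (   272)  CGG 26.6 (   338)  CGU  8.6 (   109)
CUA  9.2 (   117)  CUC 18.8 (   238)  CUG 19.8 (   251)  CUU  9.4 (   119)
GAA  8.5 (   108)  GAC 24.7 (   314)  GAG 23.7 (   301)  GAU 10.8 (   137)
GCA  9.4 (   119)  GCC 21.4 (   271)  GCG 21.3 (   270)  GCU 12.1 (   154)
GGA 10.6 (   135)  GGC 27.3 (   347)  GGG 24.7 (   313)  GGU 10.3 (   131)
GUA  8.3 (   105)  GUC 16.2 (   205)  GUG 20.2 (   256)  GUU  9.8 (   125)
UAA  1.2 (    15)  UAC 27.2 (   345)  UAG  1.3 (    16)  UAU 11.5 (   146)
UCA 10.6 (   135)  UCC 22.8 (   289)  UCG 20.3 (   257)  UCU 12.8 (   162)
UGA  1.3 (    16)  UGC 18.9 (   240)  UGG 19.1 (   242)  UGU  8.4 (   106)
UUA  9.3 (   118)  UUC 23.6 (   300)  UUG 28.3 (   359)  UUU 11.8 (   150)
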