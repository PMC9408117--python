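locus,size_min,size_max,chromosome,tna,ar,pic
Inra023,195,221,1,17,10.25,0.87
Inra063,168,208,14,28,10.4,0.82
OarCP49,71,137,17,31,13.34,0.85
OarFCB304,145,201,19,24,8.96,0.76
OarFCB20,85,121,2,19,10.26,0.84
MAF65,113,139,15,21,7.75,0.75
ILST087,134,184,6,26,13.17,0.88
OarAE119,145,185,19,20,9.51,0.82
MCM527,164,190,5,17,7.89,0.78
MAF214,182,262,16,38,6.96,0.61
OarAE129,135,165,5,16,5.26,0.63
OarCP34,93,117,3,18,6.62,0.77
OarAE54,120,152,25,19,10.44,0.82
TGLA,125,163,12,16,9.67,0.84
URB,159,211,13,24,9.93,0.86
CSRD,208,262,14,28,9.74,0.84
HSC,260,296,20,21,9.33,0.85
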