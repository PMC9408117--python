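,LAM,FOZ,ALP,BRO,DM,CRO,NTH,QFO,SS,BAR,APP
LAM,0.0,1.652,1.757,1.753,5.949,2.752,3.069,2.503,2.118,3.165,3.22
FOZ,1.652,0.0,0.932,1.116,6.402,2.841,3.141,2.829,2.266,3.023,3.852
ALP,1.757,0.932,0.0,1.679,5.635,3.102,3.801,3.146,3.074,3.325,5.869
BRO,1.753,1.116,1.679,0.0,6.442,3.391,4.471,3.633,3.208,3.258,2.954
DM,5.949,6.402,5.635,6.442,0.0,2.47,3.578,3.508,4.055,3.378,6.609
CRO,2.752,2.841,3.102,3.391,2.47,0.0,0.458,0.692,0.925,1.15,3.34
NTH,3.069,3.141,3.801,4.471,3.578,0.458,0.0,0.54,0.717,1.39,3.756
QFO,2.503,2.829,3.146,3.633,3.508,0.692,0.54,0.0,0.998,0.864,3.899
SS,2.118,2.266,3.074,3.208,4.055,0.925,0.717,0.998,0.0,2.149,2.366
BAR,3.165,3.023,3.325,3.258,3.378,1.15,1.39,0.864,2.149,0.0,4.166
APP,3.22,3.852,5.869,2.954,6.609,3.34,3.756,3.899,2.366,4.166,0.0
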