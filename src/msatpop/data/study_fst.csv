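,LAM,FOZ,ALP,BRO,DM,CRO,NTH,QFO,SS,BAR,APP
LAM,0.0,0.042,0.038,0.039,0.102,0.118,0.114,0.105,0.118,0.118,0.126
FOZ,0.042,0.0,0.053,0.041,0.098,0.11,0.098,0.096,0.111,0.11,0.116
ALP,0.038,0.053,0.0,0.04,0.114,0.13,0.126,0.124,0.132,0.137,0.147
BRO,0.039,0.041,0.04,0.0,0.105,0.114,0.113,0.106,0.122,0.116,0.128
DM,0.102,0.098,0.114,0.105,0.0,0.029,0.034,0.021,0.043,0.032,0.073
CRO,0.118,0.11,0.13,0.114,0.029,0.0,0.018,0.006,0.023,0.008,0.07
NTH,0.114,0.098,0.126,0.113,0.034,0.018,0.0,0.014,0.02,0.024,0.069
QFO,0.105,0.096,0.124,0.106,0.021,0.006,0.014,0.0,0.018,0.005,0.052
SS,0.118,0.111,0.132,0.122,0.043,0.023,0.02,0.018,0.0,0.028,0.057
BAR,0.118,0.11,0.137,0.116,0.032,0.008,0.024,0.005,0.028,0.0,0.067
APP,0.126,0.116,0.147,0.128,0.073,0.07,0.069,0.052,0.057,0.067,0.0
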