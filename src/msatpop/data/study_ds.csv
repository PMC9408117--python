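,LAM,FOZ,ALP,BRO,DM,CRO,NTH,QFO,SS,BAR,APP
LAM,0.0,0.186,0.142,0.162,0.486,0.541,0.532,0.509,0.564,0.555,0.534
FOZ,0.186,0.0,0.205,0.169,0.475,0.51,0.461,0.474,0.536,0.521,0.492
ALP,0.142,0.205,0.0,0.147,0.482,0.538,0.528,0.538,0.563,0.585,0.571
BRO,0.162,0.169,0.147,0.0,0.478,0.499,0.501,0.492,0.558,0.521,0.523
DM,0.486,0.475,0.482,0.478,0.0,0.132,0.156,0.108,0.201,0.146,0.298
CRO,0.541,0.51,0.538,0.499,0.132,0.0,0.079,0.03,0.104,0.037,0.275
NTH,0.532,0.461,0.528,0.501,0.156,0.079,0.0,0.065,0.09,0.105,0.273
QFO,0.509,0.474,0.538,0.492,0.108,0.03,0.065,0.0,0.089,0.025,0.213
SS,0.564,0.536,0.563,0.558,0.201,0.104,0.09,0.089,0.0,0.125,0.23
BAR,0.555,0.521,0.585,0.521,0.146,0.037,0.105,0.025,0.125,0.0,0.267
APP,0.534,0.492,0.571,0.523,0.298,0.275,0.273,0.213,0.23,0.267,0.0
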