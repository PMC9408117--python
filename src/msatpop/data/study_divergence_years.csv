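,LAM,FOZ,ALP,BRO,DM,CRO,NTH,QFO,SS,BAR,APP
LAM,0.0,2753.3,2928.3,2921.7,9915.0,4586.7,5115.0,4171.7,3530.0,5275.0,5366.7
FOZ,2753.3,0.0,1553.3,1860.0,10670.0,4735.0,5235.0,4715.0,3776.7,5038.3,6420.0
ALP,2928.3,1553.3,0.0,2798.8,9392.0,5169.2,6334.2,5243.7,5123.7,5542.5,9781.8
BRO,2921.7,1860.0,2798.8,0.0,10736.3,5652.4,7451.7,6055.0,5346.4,5430.6,4922.8
DM,9915.0,10670.0,9392.0,10736.3,0.0,4117.4,5963.3,5847.4,6758.7,5629.6,11015.0
CRO,4586.7,4735.0,5169.2,5652.4,4117.4,0.0,763.8,1154.0,1541.2,1916.6,5566.3
NTH,5115.0,5235.0,6334.2,7451.7,5963.3,763.8,0.0,900.8,1195.6,2316.3,6260.8
QFO,4171.7,4715.0,5243.7,6055.0,5847.4,1154.0,900.8,0.0,1663.6,1440.8,6498.1
SS,3530.0,3776.7,5123.7,5346.4,6758.7,1541.2,1195.6,1663.6,0.0,3582.3,3943.4
BAR,5275.0,5038.3,5542.5,5430.6,5629.6,1916.6,2316.3,1440.8,3582.3,0.0,6943.2
APP,5366.7,6420.0,9781.8,4922.8,11015.0,5566.3,6260.8,6498.1,3943.4,6943.2,0.0
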