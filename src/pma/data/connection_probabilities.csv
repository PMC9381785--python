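pre_class,post_class,p
deep-PC,deep-PC,0.0015
deep-PC,superficial-PC,0.0015
superficial-PC,deep-PC,0.0015
superficial-PC,superficial-PC,0.0015
deep-PC,OLM,0.000933
deep-PC,Trilaminar,0.000933
deep-PC,BP,0.000933
deep-PC,CCKBC,0.000933
deep-PC,PVBC,0.000933
deep-PC,AA,0.000933
deep-PC,IVY,0.000933
deep-PC,BS,0.000933
deep-PC,PPA,0.000933
superficial-PC,OLM,0.000933
superficial-PC,Trilaminar,0.000933
superficial-PC,BP,0.000933
superficial-PC,CCKBC,0.000933
superficial-PC,PVBC,0.000933
superficial-PC,AA,0.000933
superficial-PC,IVY,0.000933
superficial-PC,BS,0.000933
superficial-PC,PPA,0.000933
CCKBC,deep-PC,0.005
CCKBC,superficial-PC,0.005
PVBC,deep-PC,0.005
PVBC,superficial-PC,0.005
AA,deep-PC,0.005
AA,superficial-PC,0.005
OLM,deep-PC,0.003
OLM,superficial-PC,0.003
BP,deep-PC,0.003
BP,superficial-PC,0.003
Trilaminar,deep-PC,0.003
Trilaminar,superficial-PC,0.003
IVY,deep-PC,0.005
IVY,superficial-PC,0.005
BS,deep-PC,0.005
BS,superficial-PC,0.005
SCA,deep-PC,0.003
SCA,superficial-PC,0.003
PPA,deep-PC,0.003
PPA,superficial-PC,0.003
NG,deep-PC,0.002
NG,superficial-PC,0.002
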