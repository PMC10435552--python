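substance,classes,loq_ng_g,ld50_ug_bee,ld50_bound
acetamiprid,I,0.10,14.53,exact
azoxystrobin,F,1.00,25.00,greater_than
boscalid,F,0.01,100.00,exact
chlorothalonil,F,1.00,40.00,greater_than
difenoconazole,F,0.01,177.00,greater_than
fluopyram,F;N,1.00,102.30,greater_than
fluxapyroxad,F,1.00,110.90,greater_than
picoxystrobin,F,0.10,200.00,greater_than
tebuconazole,F,1.00,83.05,greater_than
dimethoate,I;A,1.00,0.10,exact
omethoate,I;A,5.00,0.05,exact
prosulfocarb,H,1.00,103.40,exact
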