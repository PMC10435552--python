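nest_id,substance,concentration_ng_g
A2,acetamiprid,0.37
A4,acetamiprid,0.83
A6,acetamiprid,0.28
A7,acetamiprid,0.33
A8,acetamiprid,0.12
A9,acetamiprid,0.11
A10,acetamiprid,1.16
A11,acetamiprid,0.11
A12,acetamiprid,0.22
A2,azoxystrobin,22.55
A3,azoxystrobin,10.60
A6,azoxystrobin,8.95
A7,azoxystrobin,5.50
A8,azoxystrobin,8.90
A9,azoxystrobin,12.00
A10,azoxystrobin,198.40
A1,boscalid,15.45
A2,boscalid,10.20
A3,boscalid,15.75
A5,boscalid,16.95
A6,boscalid,11.25
A11,boscalid,7.90
A12,boscalid,5.90
A6,chlorothalonil,2.15
A7,difenoconazole,6.55
A10,difenoconazole,40.30
A2,fluopyram,4.93
A4,fluopyram,41.10
A6,fluopyram,2.88
A7,fluopyram,12.23
A11,fluopyram,10.03
A12,fluopyram,2.08
A2,fluxapyroxad,2.05
A6,fluxapyroxad,2.75
A11,fluxapyroxad,2.40
A12,fluxapyroxad,6.55
A1,picoxystrobin,3.70
A1,tebuconazole,24.35
A3,tebuconazole,16.20
A7,tebuconazole,10.45
A8,tebuconazole,18.55
A10,tebuconazole,6.30
A2,dimethoate,2.75
A4,dimethoate,12.05
A6,dimethoate,7.85
A7,dimethoate,4.35
A8,dimethoate,17.08
A11,dimethoate,1.70
A12,dimethoate,3.00
A2,omethoate,1.13
A4,omethoate,6.33
A6,omethoate,4.98
A7,omethoate,1.40
A8,omethoate,9.13
A12,omethoate,1.33
A6,prosulfocarb,26.40
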