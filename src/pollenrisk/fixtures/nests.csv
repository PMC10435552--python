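nest_id,provision_mass_mg,energetic_value_kj_g
A1,246.50,18.62
A2,241.80,18.02
A3,239.80,17.74
A4,233.20,18.32
A5,252.20,18.77
A6,216.30,17.58
A7,238.90,17.15
A8,241.30,18.18
A9,212.20,18.19
A10,254.30,17.46
A11,229.50,18.08
A12,231.90,17.41
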