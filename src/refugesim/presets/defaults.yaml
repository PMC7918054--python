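# Canonical simulation defaults (full-scale lattice).
AE: 0.86
T: 0.50
CL: 0.20
Ro_Sf: 400.00
Ro_Ha: 725.06
NM: 0.25
IM: 0.99
RF: 0.0625
IF: 500
rows: 1000
cols: 1000
steps: 80
resistance_model: tracked
alpha11: 0.63
alpha12: 0.58
alpha21: 0.46
alpha22: 0.90
beta11: 0.31
beta12: 0.11
beta21: 0.38
beta22: 0.16
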