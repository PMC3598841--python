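term,value
constant,0.071
MO2,0.036
MO3,0.161
SC2,0.082
SC3,0.152
UA2,0.032
UA3,0.057
PD2,0.086
PD3,0.329
AD2,0.124
AD3,0.325
N3,0.234
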