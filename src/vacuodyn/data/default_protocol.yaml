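# Standard hypo-osmotic perfusion protocol: 450 mOsmol/Kgw iso-osmotic
# plateau for 300 s, then a measured single-exponential decay of the
# external osmolality toward 258.8 mOsmol/Kgw.
C0: 450.0
t_switch: 300.0
B: 731.5
t_star: 237.2
Ce_star: 258.8
t_end: 900.0
direction: hypo
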