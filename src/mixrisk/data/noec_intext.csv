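pesticide,noec_mg_kg
Chlorantraniliprole,0.19
Oxyfluorfen,1.25
Phosmet,0.81
Acetamiprid,0.27
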