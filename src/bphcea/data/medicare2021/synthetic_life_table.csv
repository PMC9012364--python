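# SYNTHETIC male life table (annual death probability by age), magnitudes of
# recent US male national life tables; no rates were published with the model.
age,qx
60.0,0.0112
61.0,0.012
62.0,0.0128
63.0,0.0137
64.0,0.0146
65.0,0.0157
66.0,0.017
67.0,0.0183
68.0,0.0197
69.0,0.0214
70.0,0.0232
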