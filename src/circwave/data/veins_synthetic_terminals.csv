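segment_id,flow_fraction
105,0.085
115,0.085
106,0.02
116,0.02
113,0.0225
126,0.0225
117,0.035
124,0.035
118,0.0125
125,0.0125
129,0.13
131,0.14
133,0.09
134,0.09
136,0.02
146,0.03
147,0.03
150,0.025
151,0.025
152,0.035
153,0.035
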