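segment_id,flow_fraction
3,0.175
4,0.65
15,0.09
16,0.015
24,0.0245
25,0.0105
26,0.035
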