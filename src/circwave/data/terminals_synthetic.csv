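segment_id,flow_fraction,venous_segment_id
5,0.085,105
15,0.085,115
6,0.02,106
16,0.02,116
13,0.0225,113
26,0.0225,126
17,0.035,117
24,0.035,124
18,0.0125,118
25,0.0125,125
29,0.13,129
31,0.14,131
33,0.09,133
34,0.09,134
36,0.02,136
46,0.03,146
47,0.03,147
50,0.025,150
51,0.025,151
52,0.035,152
53,0.035,153
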