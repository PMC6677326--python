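id,name,class,length_m,r0_prox_m,r0_dist_m,k,b,p0_mmHg,pext_mmHg,prox_node,dist_node
101,vena_cava,vein,0.04,0.012,0.012,10.0,0.02,1.1,0,VN1,VAOROOT
102,vena_cava_a,vein,0.02,0.012,0.012,10.0,0.02,1.1,0,VN2,VN1
103,brachiocephalic_vein,vein,0.034,0.00812,0.00868,10.0,0.02,1.1,0,VRBR,VN2
105,r_carotid_vein,vein,0.136,0.00476,0.00588,10.0,0.02,1.1,0,VRCAR_T,VRBR
107,r_subclavian_a_vein,vein,0.034,0.0056,0.00588,10.0,0.02,1.1,0,VRS1,VRBR
106,r_vertebral_vein,vein,0.148,0.00224,0.0028,10.0,0.02,1.1,0,VRVER_T,VRS1
108,r_subclavian_b_vein,vein,0.068,0.00532,0.0056,10.0,0.02,1.1,0,VRS2,VRS1
109,r_axillary_vein,vein,0.061,0.00476,0.00504,10.0,0.02,1.1,0,VRA1,VRS2
110,r_brachial_vein,vein,0.2,0.00392,0.00476,10.0,0.02,1.1,0,VRB1,VRA1
111,r_radial_vein,vein,0.117,0.00224,0.00238,10.0,0.02,1.1,0,VRR1,VRB1
113,r_radial_b_vein,vein,0.117,0.00238,0.00238,10.0,0.02,1.1,0,VRRAD_T,VRR1
112,r_ulnar_a_vein,vein,0.067,0.0028,0.00294,10.0,0.02,1.1,0,VRU1,VRB1
117,r_ulnar_b_vein,vein,0.171,0.00294,0.00294,10.0,0.02,1.1,0,VRULN_T,VRU1
118,r_interosseous_vein,vein,0.079,0.00154,0.00154,10.0,0.02,1.1,0,VRINT_T,VRU1
114,vena_cava_b,vein,0.039,0.012,0.012,10.0,0.02,1.1,0,VN3,VN2
115,l_carotid_vein,vein,0.136,0.00476,0.00588,10.0,0.02,1.1,0,VLCAR_T,VN2
119,l_subclavian_a_vein,vein,0.034,0.0056,0.00588,10.0,0.02,1.1,0,VLS1,VN3
116,l_vertebral_vein,vein,0.148,0.00224,0.0028,10.0,0.02,1.1,0,VLVER_T,VLS1
127,l_subclavian_b_vein,vein,0.068,0.00532,0.0056,10.0,0.02,1.1,0,VLS2,VLS1
120,l_axillary_vein,vein,0.061,0.00476,0.00504,10.0,0.02,1.1,0,VLA1,VLS2
121,l_brachial_vein,vein,0.2,0.00392,0.00476,10.0,0.02,1.1,0,VLB1,VLA1
122,l_radial_vein,vein,0.117,0.00224,0.00238,10.0,0.02,1.1,0,VLR1,VLB1
126,l_radial_b_vein,vein,0.117,0.00238,0.00238,10.0,0.02,1.1,0,VLRAD_T,VLR1
123,l_ulnar_a_vein,vein,0.067,0.0028,0.00294,10.0,0.02,1.1,0,VLU1,VLB1
124,l_ulnar_b_vein,vein,0.171,0.00294,0.00294,10.0,0.02,1.1,0,VLULN_T,VLU1
125,l_interosseous_vein,vein,0.079,0.00154,0.00154,10.0,0.02,1.1,0,VLINT_T,VLU1
104,thoracic_ivc_a,vein,0.052,0.012,0.012,10.0,0.02,1.1,0,VN4,VN3
135,thoracic_ivc_b,vein,0.104,0.012,0.012,10.0,0.02,1.1,0,VN5,VN4
137,abdominal_ivc_a,vein,0.053,0.012,0.012,10.0,0.02,1.1,0,VN6,VN5
129,celiac_vein,vein,0.02,0.0063,0.0063,10.0,0.02,1.1,0,VCEL_T,VN6
138,abdominal_ivc_b,vein,0.02,0.012,0.012,10.0,0.02,1.1,0,VN7,VN6
131,sup_mesenteric_vein,vein,0.059,0.00672,0.00672,10.0,0.02,1.1,0,VSME_T,VN7
139,abdominal_ivc_c,vein,0.02,0.012,0.012,10.0,0.02,1.1,0,VN8,VN7
133,l_renal_vein,vein,0.032,0.00448,0.00448,10.0,0.02,1.1,0,VLREN_T,VN8
134,r_renal_vein,vein,0.032,0.00448,0.00448,10.0,0.02,1.1,0,VRREN_T,VN8
140,abdominal_ivc_d,vein,0.106,0.01134,0.012,10.0,0.02,1.1,0,VN9,VN8
136,inf_mesenteric_vein,vein,0.05,0.0028,0.0028,10.0,0.02,1.1,0,VIME_T,VN9
141,abdominal_ivc_e,vein,0.02,0.011038,0.01134,10.0,0.02,1.1,0,VNBIF,VN9
142,l_common_iliac_vein,vein,0.058,0.0049,0.00518,10.0,0.02,1.1,0,VLI1,VNBIF
146,l_internal_iliac_vein,vein,0.05,0.0035,0.0035,10.0,0.02,1.1,0,VLII_T,VLI1
144,l_external_iliac_vein,vein,0.144,0.00406,0.00448,10.0,0.02,1.1,0,VLI2,VLI1
148,l_femoral_vein,vein,0.17,0.00364,0.00378,10.0,0.02,1.1,0,VLFEM_T,VLI2
154,l_popliteal_vein,vein,0.273,0.00336,0.00364,10.0,0.02,1.1,0,VLP1,VLFEM_T
150,l_ant_tibial_vein,vein,0.343,0.00238,0.00238,10.0,0.02,1.1,0,VLAT_T,VLP1
152,l_post_tibial_vein,vein,0.321,0.00266,0.00266,10.0,0.02,1.1,0,VLPT_T,VLP1
143,r_common_iliac_vein,vein,0.058,0.0049,0.00518,10.0,0.02,1.1,0,VRI1,VNBIF
147,r_internal_iliac_vein,vein,0.05,0.0035,0.0035,10.0,0.02,1.1,0,VRII_T,VRI1
145,r_external_iliac_vein,vein,0.144,0.00406,0.00448,10.0,0.02,1.1,0,VRI2,VRI1
149,r_femoral_vein,vein,0.17,0.00364,0.00378,10.0,0.02,1.1,0,VRFEM_T,VRI2
155,r_popliteal_vein,vein,0.273,0.00336,0.00364,10.0,0.02,1.1,0,VRP1,VRFEM_T
151,r_ant_tibial_vein,vein,0.343,0.00238,0.00238,10.0,0.02,1.1,0,VRAT_T,VRP1
153,r_post_tibial_vein,vein,0.321,0.00266,0.00266,10.0,0.02,1.1,0,VRPT_T,VRP1
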