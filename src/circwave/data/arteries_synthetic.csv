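id,name,class,length_m,r0_prox_m,r0_dist_m,k,b,p0_mmHg,pext_mmHg,prox_node,dist_node
1,ascending_aorta,artery,0.04,0.01566,0.01512,1.1,0.02,105.0,0,AOROOT,N1
2,aortic_arch_a,artery,0.02,0.01512,0.01458,1.1,0.02,105.0,0,N1,N2
3,brachiocephalic,artery,0.034,0.0062,0.0058,7.0,0.02,105.0,0,N2,RBR
5,r_carotid,artery,0.136,0.0042,0.0034,8.0,0.02,105.0,0,RBR,RCAR_T
7,r_subclavian_a,artery,0.034,0.0042,0.004,7.0,0.02,105.0,0,RBR,RS1
6,r_vertebral,artery,0.148,0.002,0.0016,7.0,0.02,105.0,0,RS1,RVER_T
8,r_subclavian_b,artery,0.068,0.004,0.0038,7.0,0.02,105.0,0,RS1,RS2
9,r_axillary,artery,0.061,0.0036,0.0034,7.0,0.02,105.0,0,RS2,RA1
10,r_brachial,artery,0.2,0.0034,0.0028,7.0,0.02,105.0,0,RA1,RB1
11,r_radial,artery,0.117,0.0017,0.0016,7.0,0.02,105.0,0,RB1,RR1
13,r_radial_b,artery,0.117,0.0017,0.0017,7.0,0.02,105.0,0,RR1,RRAD_T
12,r_ulnar_a,artery,0.067,0.0021,0.002,7.0,0.02,105.0,0,RB1,RU1
17,r_ulnar_b,artery,0.171,0.0021,0.0021,7.0,0.02,105.0,0,RU1,RULN_T
18,r_interosseous,artery,0.079,0.0011,0.0011,7.0,0.02,105.0,0,RU1,RINT_T
14,aortic_arch_b,artery,0.039,0.01458,0.013716,1.1,0.02,105.0,0,N2,N3
15,l_carotid,artery,0.136,0.0042,0.0034,8.0,0.02,105.0,0,N2,LCAR_T
19,l_subclavian_a,artery,0.034,0.0042,0.004,7.0,0.02,105.0,0,N3,LS1
16,l_vertebral,artery,0.148,0.002,0.0016,7.0,0.02,105.0,0,LS1,LVER_T
27,l_subclavian_b,artery,0.068,0.004,0.0038,7.0,0.02,105.0,0,LS1,LS2
20,l_axillary,artery,0.061,0.0036,0.0034,7.0,0.02,105.0,0,LS2,LA1
21,l_brachial,artery,0.2,0.0034,0.0028,7.0,0.02,105.0,0,LA1,LB1
22,l_radial,artery,0.117,0.0017,0.0016,7.0,0.02,105.0,0,LB1,LR1
26,l_radial_b,artery,0.117,0.0017,0.0017,7.0,0.02,105.0,0,LR1,LRAD_T
23,l_ulnar_a,artery,0.067,0.0021,0.002,7.0,0.02,105.0,0,LB1,LU1
24,l_ulnar_b,artery,0.171,0.0021,0.0021,7.0,0.02,105.0,0,LU1,LULN_T
25,l_interosseous,artery,0.079,0.0011,0.0011,7.0,0.02,105.0,0,LU1,LINT_T
4,thoracic_aorta_a,artery,0.052,0.013716,0.012636,1.1,0.02,105.0,0,N3,N4
35,thoracic_aorta_b,artery,0.104,0.012636,0.0108,1.1,0.02,105.0,0,N4,N5
37,abdominal_aorta_a,artery,0.053,0.0108,0.009936,1.1,0.02,105.0,0,N5,N6
29,celiac,artery,0.02,0.0045,0.0045,7.0,0.02,105.0,0,N6,CEL_T
38,abdominal_aorta_b,artery,0.02,0.009936,0.00972,1.1,0.02,105.0,0,N6,N7
31,sup_mesenteric,artery,0.059,0.0048,0.0048,7.0,0.02,105.0,0,N7,SME_T
39,abdominal_aorta_c,artery,0.02,0.00972,0.009504,1.1,0.02,105.0,0,N7,N8
33,l_renal,artery,0.032,0.0032,0.0032,7.0,0.02,105.0,0,N8,LREN_T
34,r_renal,artery,0.032,0.0032,0.0032,7.0,0.02,105.0,0,N8,RREN_T
40,abdominal_aorta_d,artery,0.106,0.009504,0.0081,1.1,0.02,105.0,0,N8,N9
36,inf_mesenteric,artery,0.05,0.002,0.002,7.0,0.02,105.0,0,N9,IME_T
41,abdominal_aorta_e,artery,0.02,0.0081,0.007884,1.1,0.02,105.0,0,N9,NBIF
42,l_common_iliac,artery,0.058,0.0037,0.0035,30.0,0.02,105.0,0,NBIF,LI1
46,l_internal_iliac,artery,0.05,0.0025,0.0025,30.0,0.02,105.0,0,LI1,LII_T
44,l_external_iliac,artery,0.144,0.0032,0.0029,30.0,0.02,105.0,0,LI1,LI2
48,l_femoral,artery,0.17,0.0027,0.0026,30.0,0.02,105.0,0,LI2,LFEM_T
54,l_popliteal,artery,0.273,0.0026,0.0024,30.0,0.02,105.0,0,LFEM_T,LP1
50,l_ant_tibial,artery,0.343,0.0017,0.0017,30.0,0.02,105.0,0,LP1,LAT_T
52,l_post_tibial,artery,0.321,0.0019,0.0019,30.0,0.02,105.0,0,LP1,LPT_T
43,r_common_iliac,artery,0.058,0.0037,0.0035,30.0,0.02,105.0,0,NBIF,RI1
47,r_internal_iliac,artery,0.05,0.0025,0.0025,30.0,0.02,105.0,0,RI1,RII_T
45,r_external_iliac,artery,0.144,0.0032,0.0029,30.0,0.02,105.0,0,RI1,RI2
49,r_femoral,artery,0.17,0.0027,0.0026,30.0,0.02,105.0,0,RI2,RFEM_T
55,r_popliteal,artery,0.273,0.0026,0.0024,30.0,0.02,105.0,0,RFEM_T,RP1
51,r_ant_tibial,artery,0.343,0.0017,0.0017,30.0,0.02,105.0,0,RP1,RAT_T
53,r_post_tibial,artery,0.321,0.0019,0.0019,30.0,0.02,105.0,0,RP1,RPT_T
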