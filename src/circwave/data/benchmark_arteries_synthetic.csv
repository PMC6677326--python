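id,name,class,length_m,r0_prox_m,r0_dist_m,k,b,p0_mmHg,pext_mmHg,prox_node,dist_node
1+2,aorta_asc_arch,artery,0.06,0.01566,0.01458,1.1,0.02,105.0,0,AOROOT,N2
3,brachiocephalic,artery,0.034,0.0062,0.0058,7.0,0.02,105.0,0,N2,BRA_T
15,l_carotid,artery,0.136,0.0042,0.0034,8.0,0.02,105.0,0,N2,LCAR_T
14,aortic_arch_b,artery,0.039,0.01458,0.013716,1.1,0.02,105.0,0,N2,N3
19+27,l_subclavian,artery,0.102,0.0042,0.0038,7.0,0.02,105.0,0,N3,LS2
4,thoracic_aorta,artery,0.156,0.013716,0.0108,1.1,0.02,105.0,0,N3,N4
16,l_vertebral,artery,0.148,0.002,0.0016,7.0,0.02,105.0,0,LS2,LVER_T
20,l_axillary,artery,0.061,0.0036,0.0034,7.0,0.02,105.0,0,LS2,LA1
21,l_brachial,artery,0.2,0.0034,0.0028,7.0,0.02,105.0,0,LA1,LB1
22,l_radial,artery,0.117,0.0017,0.0016,7.0,0.02,105.0,0,LB1,LR1
26,l_radial_b,artery,0.117,0.0017,0.0017,7.0,0.02,105.0,0,LR1,LRAD_T
23,l_ulnar_a,artery,0.067,0.0021,0.002,7.0,0.02,105.0,0,LB1,LU1
24,l_ulnar_b,artery,0.171,0.0021,0.0021,7.0,0.02,105.0,0,LU1,LULN_T
25,l_interosseous,artery,0.079,0.0011,0.0011,7.0,0.02,105.0,0,LU1,LINT_T
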