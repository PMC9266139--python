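segment,layer,area_frac,mass_frac,cp_j_per_kg_k,basal_flow_l_per_h_kg,q_basal_frac,work_frac,shiver_frac
head,skin,0.0589,0.0032500000000000003,3680,2.8,0.003,0.0,0.0
head,fat,0.0589,0.0078000000000000005,2300,0.3,0.002,0.0,0.0
head,muscle,0.0589,0.009100000000000002,3768,0.6,0.01,0.0,0.02
head,core,0.0589,0.04225000000000001,3850,14.0,0.17,0.0,0.0
head,artery,0.0589,0.0013000000000000002,3850,60.0,0.0,0.0,0.0
head,vein,0.0589,0.0013000000000000002,3850,60.0,0.0,0.0,0.0
neck,skin,0.0155,0.0009600000000000001,3680,3.8,0.001,0.0,0.0
neck,core,0.0155,0.014400000000000001,3697,2.5,0.008,0.0,0.0
neck,artery,0.0155,0.0003200000000000001,3850,60.0,0.0,0.0,0.0
neck,vein,0.0155,0.0003200000000000001,3850,60.0,0.0,0.0,0.0
chest,skin,0.0937,0.008940000000000002,3680,3.8,0.002,0.0,0.0
chest,core,0.0937,0.13410000000000002,3697,10.0,0.24,0.1,0.25
chest,artery,0.0937,0.0029800000000000004,3850,60.0,0.0,0.0,0.0
chest,vein,0.0937,0.0029800000000000004,3850,60.0,0.0,0.0,0.0
back,skin,0.0862,0.008940000000000002,3680,3.8,0.002,0.0,0.0
back,core,0.0862,0.13410000000000002,3697,2.5,0.14,0.12,0.25
back,artery,0.0862,0.0029800000000000004,3850,60.0,0.0,0.0,0.0
back,vein,0.0862,0.0029800000000000004,3850,60.0,0.0,0.0,0.0
pelvis,skin,0.1181,0.011820000000000002,3680,3.8,0.003,0.0,0.0
pelvis,fat,0.1181,0.043340000000000004,2300,0.3,0.005,0.0,0.0
pelvis,muscle,0.1181,0.07486000000000001,3768,0.6,0.05,0.12,0.2
pelvis,core,0.1181,0.05910000000000001,3697,18.0,0.126,0.0,0.0
pelvis,artery,0.1181,0.003940000000000001,3850,60.0,0.0,0.0,0.0
pelvis,vein,0.1181,0.003940000000000001,3850,60.0,0.0,0.0,0.0
left_shoulder,skin,0.0514,0.0025200000000000005,3680,3.8,0.0015,0.0,0.0
left_shoulder,core,0.0514,0.023940000000000003,3000,0.9,0.02,0.06,0.03
left_shoulder,artery,0.0514,0.0005600000000000001,3850,60.0,0.0,0.0,0.0
left_shoulder,vein,0.0514,0.0005600000000000001,3850,60.0,0.0,0.0,0.0
left_shoulder,superficial_vein,0.0514,0.00042000000000000007,3850,2.0,0.0,0.0,0.0
right_shoulder,skin,0.0514,0.0025200000000000005,3680,3.8,0.0015,0.0,0.0
right_shoulder,core,0.0514,0.023940000000000003,3000,0.9,0.02,0.06,0.03
right_shoulder,artery,0.0514,0.0005600000000000001,3850,60.0,0.0,0.0,0.0
right_shoulder,vein,0.0514,0.0005600000000000001,3850,60.0,0.0,0.0,0.0
right_shoulder,superficial_vein,0.0514,0.00042000000000000007,3850,2.0,0.0,0.0,0.0
left_arm,skin,0.0337,0.0015300000000000001,3680,3.8,0.001,0.0,0.0
left_arm,core,0.0337,0.014535000000000001,3000,0.9,0.013,0.05,0.02
left_arm,artery,0.0337,0.0003400000000000001,3850,60.0,0.0,0.0,0.0
left_arm,vein,0.0337,0.0003400000000000001,3850,60.0,0.0,0.0,0.0
left_arm,superficial_vein,0.0337,0.00025500000000000007,3850,2.0,0.0,0.0,0.0
right_arm,skin,0.0337,0.0015300000000000001,3680,3.8,0.001,0.0,0.0
right_arm,core,0.0337,0.014535000000000001,3000,0.9,0.013,0.05,0.02
right_arm,artery,0.0337,0.0003400000000000001,3850,60.0,0.0,0.0,0.0
right_arm,vein,0.0337,0.0003400000000000001,3850,60.0,0.0,0.0,0.0
right_arm,superficial_vein,0.0337,0.00025500000000000007,3850,2.0,0.0,0.0,0.0
left_hand,skin,0.0268,0.0005400000000000001,3680,3.8,0.001,0.0,0.0
left_hand,core,0.0268,0.005130000000000001,3000,0.9,0.004,0.01,0.0
left_hand,artery,0.0268,0.00012000000000000002,3850,60.0,0.0,0.0,0.0
left_hand,vein,0.0268,0.00012000000000000002,3850,60.0,0.0,0.0,0.0
left_hand,superficial_vein,0.0268,9.000000000000002e-05,3850,2.0,0.0,0.0,0.0
right_hand,skin,0.0268,0.0005400000000000001,3680,3.8,0.001,0.0,0.0
right_hand,core,0.0268,0.005130000000000001,3000,0.9,0.004,0.01,0.0
right_hand,artery,0.0268,0.00012000000000000002,3850,60.0,0.0,0.0,0.0
right_hand,vein,0.0268,0.00012000000000000002,3850,60.0,0.0,0.0,0.0
right_hand,superficial_vein,0.0268,9.000000000000002e-05,3850,2.0,0.0,0.0,0.0
left_thigh,skin,0.1119,0.009000000000000001,3680,3.8,0.002,0.0,0.0
left_thigh,core,0.1119,0.08550000000000002,3000,0.9,0.05,0.13,0.06
left_thigh,artery,0.1119,0.0020000000000000005,3850,60.0,0.0,0.0,0.0
left_thigh,vein,0.1119,0.0020000000000000005,3850,60.0,0.0,0.0,0.0
left_thigh,superficial_vein,0.1119,0.0015000000000000002,3850,2.0,0.0,0.0,0.0
right_thigh,skin,0.1119,0.009000000000000001,3680,3.8,0.002,0.0,0.0
right_thigh,core,0.1119,0.08550000000000002,3000,0.9,0.05,0.13,0.06
right_thigh,artery,0.1119,0.0020000000000000005,3850,60.0,0.0,0.0,0.0
right_thigh,vein,0.1119,0.0020000000000000005,3850,60.0,0.0,0.0,0.0
right_thigh,superficial_vein,0.1119,0.0015000000000000002,3850,2.0,0.0,0.0,0.0
left_leg,skin,0.06,0.0041400000000000005,3680,3.8,0.0015,0.0,0.0
left_leg,core,0.06,0.039330000000000004,3000,0.9,0.02,0.07,0.03
left_leg,artery,0.06,0.0009200000000000001,3850,60.0,0.0,0.0,0.0
left_leg,vein,0.06,0.0009200000000000001,3850,60.0,0.0,0.0,0.0
left_leg,superficial_vein,0.06,0.0006900000000000001,3850,2.0,0.0,0.0,0.0
right_leg,skin,0.06,0.0041400000000000005,3680,3.8,0.0015,0.0,0.0
right_leg,core,0.06,0.039330000000000004,3000,0.9,0.02,0.07,0.03
right_leg,artery,0.06,0.0009200000000000001,3850,60.0,0.0,0.0,0.0
right_leg,vein,0.06,0.0009200000000000001,3850,60.0,0.0,0.0,0.0
right_leg,superficial_vein,0.06,0.0006900000000000001,3850,2.0,0.0,0.0,0.0
left_foot,skin,0.03,0.0013500000000000003,3680,3.8,0.001,0.0,0.0
left_foot,core,0.03,0.012825000000000001,3000,0.9,0.004,0.01,0.0
left_foot,artery,0.03,0.00030000000000000003,3850,60.0,0.0,0.0,0.0
left_foot,vein,0.03,0.00030000000000000003,3850,60.0,0.0,0.0,0.0
left_foot,superficial_vein,0.03,0.00022500000000000002,3850,2.0,0.0,0.0,0.0
right_foot,skin,0.03,0.0013500000000000003,3680,3.8,0.001,0.0,0.0
right_foot,core,0.03,0.012825000000000001,3000,0.9,0.004,0.01,0.0
right_foot,artery,0.03,0.00030000000000000003,3850,60.0,0.0,0.0,0.0
right_foot,vein,0.03,0.00030000000000000003,3850,60.0,0.0,0.0,0.0
right_foot,superficial_vein,0.03,0.00022500000000000002,3850,2.0,0.0,0.0,0.0
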