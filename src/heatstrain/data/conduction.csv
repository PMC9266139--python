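segment,layer_a,layer_b,k_w_per_m2k
head,core,muscle,5.0
head,muscle,fat,12.0
head,fat,skin,16.0
head,artery,core,10.0
head,vein,core,10.0
head,artery,vein,2.0
neck,core,skin,5.0
neck,artery,core,10.0
neck,vein,core,10.0
neck,artery,vein,2.0
chest,core,skin,5.0
chest,artery,core,10.0
chest,vein,core,10.0
chest,artery,vein,2.0
back,core,skin,5.0
back,artery,core,10.0
back,vein,core,10.0
back,artery,vein,2.0
pelvis,core,muscle,5.0
pelvis,muscle,fat,10.0
pelvis,fat,skin,14.0
pelvis,artery,core,10.0
pelvis,vein,core,10.0
pelvis,artery,vein,2.0
left_shoulder,core,skin,6.5
left_shoulder,artery,core,10.0
left_shoulder,vein,core,10.0
left_shoulder,artery,vein,3.0
left_shoulder,superficial_vein,skin,6.0
right_shoulder,core,skin,6.5
right_shoulder,artery,core,10.0
right_shoulder,vein,core,10.0
right_shoulder,artery,vein,3.0
right_shoulder,superficial_vein,skin,6.0
left_arm,core,skin,6.5
left_arm,artery,core,10.0
left_arm,vein,core,10.0
left_arm,artery,vein,3.0
left_arm,superficial_vein,skin,6.0
right_arm,core,skin,6.5
right_arm,artery,core,10.0
right_arm,vein,core,10.0
right_arm,artery,vein,3.0
right_arm,superficial_vein,skin,6.0
left_hand,core,skin,6.5
left_hand,artery,core,10.0
left_hand,vein,core,10.0
left_hand,artery,vein,3.0
left_hand,superficial_vein,skin,6.0
right_hand,core,skin,6.5
right_hand,artery,core,10.0
right_hand,vein,core,10.0
right_hand,artery,vein,3.0
right_hand,superficial_vein,skin,6.0
left_thigh,core,skin,6.5
left_thigh,artery,core,10.0
left_thigh,vein,core,10.0
left_thigh,artery,vein,3.0
left_thigh,superficial_vein,skin,6.0
right_thigh,core,skin,6.5
right_thigh,artery,core,10.0
right_thigh,vein,core,10.0
right_thigh,artery,vein,3.0
right_thigh,superficial_vein,skin,6.0
left_leg,core,skin,6.5
left_leg,artery,core,10.0
left_leg,vein,core,10.0
left_leg,artery,vein,3.0
left_leg,superficial_vein,skin,6.0
right_leg,core,skin,6.5
right_leg,artery,core,10.0
right_leg,vein,core,10.0
right_leg,artery,vein,3.0
right_leg,superficial_vein,skin,6.0
left_foot,core,skin,6.5
left_foot,artery,core,10.0
left_foot,vein,core,10.0
left_foot,artery,vein,3.0
left_foot,superficial_vein,skin,6.0
right_foot,core,skin,6.5
right_foot,artery,core,10.0
right_foot,vein,core,10.0
right_foot,artery,vein,3.0
right_foot,superficial_vein,skin,6.0
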