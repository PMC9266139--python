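segment,clo,f_cl,i_cl
head,0.0,1.0,0.34
neck,0.3,1.093,0.34
chest,0.5,1.155,0.34
back,0.6,1.186,0.34
pelvis,1.35,1.4185,0.34
left_shoulder,0.85,1.2635,0.34
right_shoulder,0.85,1.2635,0.34
left_arm,0.6,1.186,0.34
right_arm,0.6,1.186,0.34
left_hand,0.0,1.0,0.34
right_hand,0.0,1.0,0.34
left_thigh,0.95,1.2945,0.34
right_thigh,0.95,1.2945,0.34
left_leg,0.45,1.1395,0.34
right_leg,0.45,1.1395,0.34
left_foot,1.4,1.434,0.34
right_foot,1.4,1.434,0.34
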