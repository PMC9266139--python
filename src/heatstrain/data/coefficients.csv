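name,value
cdl_l_per_h_k,75.0
csh_w_per_k2,24.4
cst_per_k,10.0
csw_w_per_k,220.0
emissivity,0.95
f_eff_radiation,0.73
hc_activity_coef,4.6
hc_activity_exp,0.39
hc_activity_threshold_met,0.85
hc_forced_coef,8.6
hc_forced_exp,0.61
hc_natural_w_per_m2k,3.2
lewis_k_per_kpa,16.5
muscle_flow_l_per_h_w,0.86
res_latent_coef,0.0173
res_ref_pressure_kpa,5.867
res_ref_temp_c,34.0
res_sensible_coef,0.0014
sdl_l_per_h_k,33.0
shiver_max_w,350.0
skin_flow_max_l_per_h_m2,130.0
skin_flow_min_l_per_h_m2,0.3
solar_absorptance,0.7
solar_clothing_attenuation,0.6
solar_projected_fraction,0.3
sst_per_k,10.0
ssw_w_per_k,30.0
sweat_local_half_range_k,10.0
sweat_max_g_per_min,20.0
w_min,0.06
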