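sample_id,sample_mass_mg,f_recovered,standard_area,standard_ug_c,delta13c_methanol
bacteria_food,10.0,0.9,1000000.0,20.0,-40.0
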