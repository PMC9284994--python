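subject,acuity,side,pattern_deg,element_length_mm,acoustic_power_W,duration_s,max_temp_rise_C,time_to_baseline_s,histology_volume_cm3,mrti_volume_cm3,included,exclusion_reason
Swine 1,Acute,Center,360,7,3,100,,,,,False,suboptimal staining
Swine 1,Acute,Right,360,7,3,100,13.00,135,2.49,0.15,False,suboptimal staining
Swine 2,Acute,Center,360,7,3,100,22.00,100,0.25,0.30,True,
Swine 2,Acute,Right,360,7,4,100,23.07,100,0.60,0.35,True,
Swine 3,Acute,Center,360,7,4,120,7,150,3.693,0.4,False,suboptimal staining
Swine 4,Acute,Right,360,7,6,180,16,180,0.92,0.9,True,
Swine 5,Subacute,Center,360,7,3,120,8,120,0.44,0.4,True,
Swine 6,Subacute,Right,360,7,3,120,9.6,120,0.48,0.45,True,
Swine 7,Subacute,Right,180,7,3,120,10,90,0.27,0.25,True,
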