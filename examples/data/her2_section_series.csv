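specimen,thickness_um,target_mean,control_mean,ratio
case_A,2,2.2,2.0,1.1
case_A,4,2.4,2.4,1.1
case_A,6,3.0,2.8,1.1
case_B,2,3.4,2.4,1.4
case_B,4,4.4,3.6,1.2
case_B,6,4.4,3.6,1.2
case_C,2,7.9,2.3,3.5
case_C,4,11.4,3.0,3.9
case_C,6,12.6,3.8,3.3
case_D,2,4.8,2.55,1.88
case_D,4,5.8,2.65,2.19
case_D,6,6.4,2.84,2.25
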