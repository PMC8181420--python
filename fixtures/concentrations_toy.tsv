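patient_id	timepoint_min	ng_per_ml
PA	0	2.5
PA	60	3.4
PA	120	4.1
PB	0	3.1
PB	60	4.0
PB	120	3.9
PC	0	2.0
PC	60	2.9
PC	120	3.6
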