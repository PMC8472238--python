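sample_id	group	body_size_cm	body_weight_g	blood_glucose_mg_dl	hematocrit_pct
5600	WT	8.2	22.7	211	46.3
5601	WT	8.6	22.6	247	45.0
5602	WT	8.1	20.0	243	41.3
5603	WT	8.4	22.5	235	45.3
5604	WT	8.0	21.2	215	41.0
5607	WT	8.1	20.6	304	42.6
5637	KO	6.9	11.5	177	50.0
5641	KO	6.5	11.4	147	47.0
5646	KO	8.3	20.5	306	47.7
5647	KO	7.9	17.0	208	46.7
5650	KO	6.9	12.1	185	42.0
5663	KO	6.5	10.2	177	45.0
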