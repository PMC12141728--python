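patient_id	virus_specificity	n_infusions	wt1_data_available	status_28d_postHCT	status_at_infusion	detectable_disease_preinfusion	early_relapse_postHCT	lymphodepletion	long_term_persist	interval_start	interval_end
1	EBV	3	False	NED	NED	False	False	False	False
2	CMV	4	True	NED	MRD	True	False	False	False
4	EBV	2	True	NED	NED	False	False	False	True
5	EBV	1	True	MRD	Overt	True	False	False	False
6	CMV	4	False	NED	NED	False	False	False	False
7	EBV	1	True	MRD	MRD	True	False	False	False
8	EBV	2	True	MRD	MRD	True	False	False	True	868	1509
9	CMV	4	True	MRD	MRD	True	False	False	False
14	EBV	2	True	NED	MRD	True	False	False	False
15	CMV	2	True	NED	NED	False	False	False	False
19	EBV	1	True	NED	Overt	True	False	False	False
23	EBV	1	True	NED	NED	False	True	False	False
26	EBV	2	True	NED	NED	False	True	True	False
27	EBV	1	True	NED	NED	False	False	True	True
28	CMV	2	True	NED	NED	False	False	True	False
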