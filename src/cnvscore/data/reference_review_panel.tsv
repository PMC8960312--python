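cnv_id	dosage_type	initial_labels	final_labels	reasons	forced_review
DEL001	loss	P,LP	P,LP	.	0
DEL002	loss	P,LP	P,LP	.	0
DEL003	loss	P,LP	P,LP	.	0
DEL004	loss	P,VUS	VUS	.	0
DEL005	loss	P,VUS	VUS	.	0
DEL006	loss	P,VUS	VUS	.	0
DEL007	loss	P,VUS	VUS	.	0
DEL008	loss	P,VUS	VUS	.	0
DEL009	loss	P,VUS	VUS	.	0
DEL010	loss	P,VUS	P,VUS	.	0
DEL011	loss	P,VUS	P,VUS	.	0
DEL012	loss	P,VUS	P,VUS	.	0
DEL013	loss	P,VUS	P,LP,VUS	.	0
DEL014	loss	LP,VUS	P	.	0
DEL015	loss	LP,VUS	P,LP,VUS	.	0
DEL016	loss	LP,VUS	P,LP,VUS	.	0
DEL017	loss	LP,VUS	P,LP,VUS	.	0
DEL018	loss	LP,VUS	LP,VUS	.	0
DEL019	loss	LP,VUS	LP,VUS	.	0
DEL020	loss	P,LP,VUS	P	.	0
DEL021	loss	P,LP,VUS	P	.	0
DEL022	loss	P,LP,VUS	P,LP,VUS	.	0
DEL023	loss	P,LP,VUS	P,LP,VUS	.	0
DEL024	loss	P,LP,VUS	P,LP,VUS	.	0
DEL025	loss	P,LP,VUS	P,LP,VUS	.	0
DEL026	loss	P,LP,VUS	P,LP,VUS	.	0
DEL027	loss	P,LP,VUS	P,LP,VUS	.	0
DEL028	loss	P,LP,VUS	P,LP,VUS	.	0
DEL029	loss	P,LP,VUS	P,VUS	.	0
DEL030	loss	P,LP,VUS	P,VUS	.	0
DEL031	loss	P,LP,VUS,LB,B	P,LP,VUS	.	0
DEL032	loss	P,LP,VUS,LB,B	P,LP,VUS	.	0
DEL033	loss	LB,VUS	VUS	.	0
DEL034	loss	LB,VUS	VUS	.	0
DEL035	loss	LB,VUS	VUS	.	0
DEL036	loss	LB,B,VUS	VUS	.	0
DEL037	loss	LB,B,VUS	LB,B,VUS	.	0
DEL038	loss	LB,B,VUS	LB,B,VUS	.	0
DEL039	loss	LB,B,VUS	LB,B,VUS	.	0
DUP001	gain	P,LP	P	.	0
DUP002	gain	P,LP	P	.	0
DUP003	gain	P,LP	P	.	0
DUP004	gain	P,LP	P	.	0
DUP005	gain	P,LP	P,LP	.	0
DUP006	gain	P,LP	P,LP	.	0
DUP007	gain	P,LP	P,LP	.	0
DUP008	gain	P,VUS	P	.	0
DUP009	gain	P,VUS	P	.	0
DUP010	gain	P,VUS	P	.	0
DUP011	gain	P,VUS	VUS	.	0
DUP012	gain	P,VUS	P,LP,VUS	.	0
DUP013	gain	P,VUS	P,VUS	.	0
DUP014	gain	LP,VUS	VUS	.	0
DUP015	gain	LP,VUS	VUS	.	0
DUP016	gain	LP,VUS	VUS	.	0
DUP017	gain	LP,VUS	P	.	0
DUP018	gain	LP,VUS	P,LP,VUS	.	0
DUP019	gain	LP,VUS	P,VUS	.	0
DUP020	gain	LP,VUS	P,LP	.	0
DUP021	gain	P,LP,VUS	P	.	0
DUP022	gain	P,LP,VUS	VUS	.	0
DUP023	gain	P,LP,VUS	VUS	.	0
DUP024	gain	P,LP,VUS	P,LP,VUS	.	0
DUP025	gain	P,LP,VUS	P,LP,VUS	.	0
DUP026	gain	P,LP,VUS	P,LP,VUS	.	0
DUP027	gain	P,LP,VUS	P,LP,VUS	.	0
DUP028	gain	P,LP,VUS	P,LP,VUS	.	0
DUP029	gain	P,LP,VUS	P,VUS	.	0
DUP030	gain	P,LP,VUS	LP,VUS	.	0
DUP031	gain	P,LP,VUS	LP,VUS	.	0
DUP032	gain	P,LP,VUS,LB,B	VUS	.	0
DUP033	gain	P,LP,VUS,LB,B	P,LP,VUS	.	0
DUP034	gain	P,LP,VUS,LB,B	LP,VUS	.	0
DUP035	gain	LB,VUS	VUS	.	0
DUP036	gain	LB,VUS	VUS	.	0
DUP037	gain	LB,VUS	LB,VUS	.	0
DUP038	gain	B,VUS	B	.	0
DUP039	gain	B,VUS	B	.	0
DUP040	gain	B,VUS	B,VUS	.	0
DUP041	gain	LB,B,VUS	VUS	.	0
DUP042	gain	LB,B,VUS	LB,B,VUS	.	0
DUP043	gain	LB,B,VUS	VUS,B	.	0
DEL_FR40	loss	VUS	P,VUS	.	1
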