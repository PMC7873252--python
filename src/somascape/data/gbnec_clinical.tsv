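sample_id	gender	age	family_history	tumor_site	jaundice	t_stage	n_stage	m_stage	tnm_stage	differentiation	status	months
GBNEC_1	Male	66	No	Bottom	Yes	3	1	0	IIIB	G3	Dead	11.03
GBNEC_2	Female	50	No	Bottom	No	4	1	0	IVB	G3	Dead	4.10
GBNEC_3	Female	65	No	Body	No	2a	0	0	IIA	G2	Dead	4.67
GBNEC_4	Male	54	No	Body	No	3	0	1	IVB	G2	Alive	124.73
GBNEC_5	Female	82	No	Bottom	No	3	2	0	IVB	G3	Dead	6.33
GBNEC_6	Female	65	No	Neck	No	1b	0	0	I	G2	Alive	44.23
GBNEC_7	Female	72	No	Neck	Yes	3	2	0	IVB	G3	Dead	2.87
GBNEC_8	Female	68	No	Neck	Yes	4	1	1	IVB	G3	Dead	1.70
GBNEC_9	Female	54	No	Neck and body	No	2a	0	0	IIA	G3	Alive	32.27
GBNEC_10	Male	66	No	Neck	No	1b	0	0	I	G3	Alive	35.30
GBNEC_11	Female	68	No	Neck	No	2a	2	0	IVB	G3	Dead	2.83
GBNEC_12	Male	59	No	Neck	Yes	3	1	0	IIIB	G3	Dead	20.07
GBNEC_13	Female	64	No	Neck and body	No	3	0	0	IIIA	G3	Dead	13.67
GBNEC_14	Female	60	No	Bottom	No	3	2	0	IVB	G3	Dead	22.67
GBNEC_15	Female	59	No	Bottom	No	3	2	0	IVB	G3	Alive	6.83
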