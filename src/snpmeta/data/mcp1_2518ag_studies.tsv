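study_id	first_author	year	country	ethnicity	cancer_type	control_source	case_aa	case_ag	case_gg	control_aa	control_ag	control_gg
liu2013	Liu	2013	China	Asian	Renal	HB	59	197	160	93	234	131
arshad2013	Arshad	2013	India	Asian	Bladder	PB	32	64	24	60	87	8
wu2013	Wu	2013	Taiwan	Asian	Cervical	HB	16	52	18	33	132	88
kucukgergin2012bla	Kucukgergin	2012	Turkey	Caucasian	Bladder	HB	67	54	21	96	83	18
singh2012	Singh	2012	India	Asian	Bladder	HB	83	101	16	81	97	22
kucukgergin2012pro	Kucukgergin	2012	Turkey	Caucasian	Prostate	HB	78	67	11	64	71	17
bektas2012	Bektas-Kayhan	2012	Turkey	Caucasian	Oral	HB	67	56	6	94	45	1
chen2011	Chen	2011	Taiwan	Asian	Oral	HB	49	112	55	80	172	92
gu2011	Gu	2011	China	Asian	Gastric	HB	94	270	244	138	268	202
kruszyna2011	Kruszyna	2011	Poland	Caucasian	Breast	PB	89	54	17	154	145	24
yeh2010	Yeh	2010	Taiwan	Asian	Hepatocellular	HB	23	48	31	80	172	92
yang2010	Yang	2010	China	Asian	Lung	PB	34	48	30	10	34	38
narter2010	Narter	2010	Turkey	Caucasian	Bladder	PB	48	16	8	40	33	3
attar2010	Attar	2010	Turkey	Caucasian	Endometrial	HB	26	17	7	124	82	5
qin2009hcc	Qin	2009	China	Asian	Hepatocellular	PB	133	182	82	185	225	61
qin2009npc	Qin	2009	China	Asian	Nasopharyngeal	PB	185	299	91	185	225	61
vazquez2009	Vazquez-Lavista	2009	Mexico	Mixed	Bladder	PB	9	35	3	18	71	37
saenz2008	Sáenz-López	2008	Spain	Caucasian	Prostate	PB	174	100	24	178	123	10
landi2006	Landi	2006	Spain	Caucasian	Colorectal	HB	161	97	18	138	97	16
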