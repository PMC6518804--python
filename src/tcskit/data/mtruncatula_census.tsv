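# Census of M. truncatula two-component-system proteins: locus tag, previously
# published name (if any), unified protein name, length (aa), closest
# A. thaliana protein, and domain string. Sections: HK (histidine kinases,
# incl. CHK cytokinin receptors and ETR ethylene receptors), HPT, RRA, RRB,
# clock-RR. Domain-string grammar: Domain(states); '-' marks an absent domain;
# '(-)' an absent motif; C-ter(n) gives the transactivation-domain length in
# aa (NA if not determined).
section	locus	previous_name	name	length	at_homolog	domains
HK	Medtr5g097410		MtCHK4	1270	AHK2	CHASE His(H) HATPase_c(N,G1,F,G2) Rec(D)
HK	Medtr3g085130		MtCHK3	1035	AHK3	CHASE His(H) HATPase_c(N,G1,F,G2) Rec(D)
HK	Medtr8g080770		MtCHK2	971	AHK3	CHASE His(H) HATPase_c(N,G1,F,G2) Rec(D)
HK	Medtr8g106150	CRE1	MtCHK1	1004	AHK4	CHASE His(H) HATPase_c(N,G1,F,G2) Rec(D)
HK	Medtr2g067240		MtCHK5	256	AHK4-like	CHASE His(H) - -
HK	Medtr5g022470		MtHK1	1201	AHK1	His(H) HATPase_c(N,G1,F,G2) Rec(D)
HK	Medtr8g075340		MtHK2	1174	AHK1	His(H) HATPase_c(N,G1,F,G2) Rec(D)
HK	Medtr1g090850		MtHK3	1051	CKI1	His(H) HATPase_c(N,G1,F,G2) Rec(D)
HK	Medtr1g087140		MtHK4	1103	CKI1	His(H) HATPase_c(N,G1,F,G2) Rec(D)
HK	Medtr3g105590		MtHK5	950	CKI2/AHK5	His(H) HATPase_c(N,G1,F,G2) Rec(D)
HK	Medtr1g013360		MtHK6	1013	CKI2/AHK5	His(H) HATPase_c(N,G1,F,G2) Rec(D)
HK	Medtr1g014670		MtHK7	390	CKI2/AHK5	His(H) - -
HK	Medtr4g031150		MtETR1	791	ETR1	EBD(D,Y,I1,P,I2,C,H) GAF His(H) HATPase_c(N,G1,F,G2) Rec(D)
HK	Medtr7g109150		MtETR2	636	ERS1	EBD(D,Y,I1,P,I2,C,H) GAF His(H) HATPase_c(N,G1,F,G2) -
HK	Medtr1g044210		MtETR3	761	ETR2	EBD(D,Y,I1,P,I2,C,H) GAF His(-) HATPase_c(-,-,-,-) Rec(D)
HK	Medtr1g073840		MtETR4	760	ETR2	EBD(D,Y,I1,P,I2,C,H) GAF His(-) HATPase_c(-,G1,-,-) Rec(D)
HK	Medtr1g079790		MtETR5	763	EIN4	EBD(D,Y,I1,P,I2,C,H) GAF His(H) HATPase_c(-,G1,-,G2) Rec(D)
HK	Medtr7g116330		MtETR6	766	EIN4	EBD(D,Y,I1,P,I2,C,H) GAF His(H) HATPase_c(-,G1,-,G2) Rec(D)
HPT	Medtr1g082290		MtHPT2	152		Hpt(H)
HPT	Medtr1g089130		MtHPT3	149		Hpt(H)
HPT	Medtr2g020770		MtHPT1	148		Hpt(H)
HPT	Medtr2g100880		MtHPT4	150		Hpt(H)
HPT	Medtr2g100900		MtHPT5	150		Hpt(H)
HPT	Medtr7g114020		MtHPT8	147		Hpt(H)
HPT	Medtr4g010160		MtHPT7	169		Hpt(N)
HPT	Medtr2g103870		MtHPT6	158		Hpt(N)
HPT	Medtr2g085155		MtHPT9	151		Hpt(R)
HPT	Medtr2g086010		MtHPT10	151		Hpt(R)
RRA	Medtr1g049100		MtRRA1	198		Rec(D)
RRA	Medtr3g015490	RR9	MtRRA9	164		Rec(D)
RRA	Medtr3g078613		MtRRA2	201		Rec(D)
RRA	Medtr3g088630		MtRRA3	235		Rec(D)
RRA	Medtr3g093860		MtRRA6	156		Rec(D)
RRA	Medtr4g106590	RR8	MtRRA8	215		Rec(D)
RRA	Medtr5g036480	RR4	MtRRA4	237		Rec(D)
RRA	Medtr6g007460		MtRRA7	184		Rec(D)
RRA	Medtr7g490310	RR5	MtRRA5	239		Rec(D)
RRA	Medtr8g038620	RR11	MtRRA11	177		Rec(D)
RRB	Medtr1g032570		MtRRB7	623		Rec(D) Myb C-ter(371)
RRB	Medtr2g034960		MtRRB6	595		Rec(D) Myb C-ter(343)
RRB	Medtr2g450070		MtRRB5	666		Rec(D) Myb C-ter(401)
RRB	Medtr3g086100		MtRRB4	570		Rec(D) Myb C-ter(319)
RRB	Medtr3g102590		MtRRB10	240		Rec(D) Myb C-ter(53)
RRB	Medtr3g106220	RR3	MtRRB3	645		Rec(D) Myb C-ter(395)
RRB	Medtr4g021760		MtRRB11	312		Rec(D) Myb C-ter(91)
RRB	Medtr4g021790		MtRRB12	274		Rec(D) Myb C-ter(54)
RRB	Medtr4g021845		MtRRB13	311		Rec(D) Myb C-ter(91)
RRB	Medtr4g021855		MtRRB14	300		Rec(D) Myb C-ter(81)
RRB	Medtr4g023980		MtRRB15	201		Rec(D) Myb C-ter(2)
RRB	Medtr4g121020	RR2	MtRRB2	680		Rec(D) Myb C-ter(414)
RRB	Medtr4g131570		MtRRB16	608		Rec(D) Myb C-ter(341)
RRB	Medtr4g131580		MtRRB17	608		Rec(D) Myb C-ter(355)
RRB	Medtr4g131600		MtRRB18	590		Rec(D) Myb C-ter(337)
RRB	Medtr5g055260		MtRRB19	268		Rec(D) Myb C-ter(65)
RRB	Medtr8g079940		MtRRB20	538		Rec(D) Myb C-ter(277)
RRB	Medtr3g102600	RR1	MtRRB1	228		Rec(E) Myb C-ter(56)
RRB	Medtr4g098870		MtRRB24	586		Rec(E) Myb C-ter(193)
RRB	Medtr5g014040		MtRRB9	543		Rec(E) Myb C-ter(180)
RRB	Medtr6g045327		MtRRB25	362		Rec(E) Myb C-ter(102)
RRB	Medtr7g026400		MtRRB26	592		Rec(E) Myb C-ter(393)
RRB	Medtr8g032710		MtRRB8	476		Rec(E) Myb C-ter(203)
RRB	Medtr8g105600		MtRRB27	764		Rec(E) Myb C-ter(519)
RRB	Medtr0450s0040		MtRRB28	537		Rec(E) Myb C-ter(316)
RRB	Medtr6g016850		MtRR31	171		Rec(E) - C-ter(NA)
RRB	Medtr8g093040		MtRR32	264		Rec(E) - C-ter(NA)
RRB	Medtr1g013160		MtRRB29	326		Rec(N) Myb C-ter(53)
RRB	Medtr1g013170		MtRRB21	497		Rec(N) Myb C-ter(254)
RRB	Medtr1g013180		MtRRB22	530		Rec(N) Myb C-ter(287)
RRB	Medtr7g117705		MtRRB23	336		Rec(N) Myb C-ter(93)
RRB	NA		MtRRB30	293		Rec(N) Myb C-ter(49)
clock-RR	Medtr1g067110		MtPRR1	744		Rec(E) CCT
clock-RR	Medtr3g037390		MtPRR2	575		Rec(E) CCT
clock-RR	Medtr3g092780		MtPRR3	685		Rec(E) CCT
clock-RR	Medtr4g061360		MtPRR4	796		Rec(E) CCT
clock-RR	Medtr4g108880		MtPRR5	630		Rec(E) CCT
clock-RR	Medtr7g118260		MtPRR6	559		Rec(E) CCT
clock-RR	Medtr8g024260		MtPRR7	585		Rec(E) CCT
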