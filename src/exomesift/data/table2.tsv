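chrom	pos	rsid	gene	codon_change	aa_change	gt_a1	gt_a2	gt_a3	gt_a4	gt_a5	method_c
1	22206649	rs989994	HSPG2	aAt/aGt	N765S	C/C	C/C	C/C	C/C	C/C	false
1	40923019	rs2272994	ZNF643	atG/atA	M46I	G/A	G/A	G/A	A/A	A/A	true
1	53320274	rs480299	ZYG11A	gaG/gaT	E76D	T/T	G/T	T/T	T/T	T/T	true
1	150679033	rs1336900	HORMAD1	aCa/aTa	T187I	G/A	G/A	G/A	G/A	G/A	true
1	150727539	rs2230061	CTSS	Cgg/Tgg	R113W	G/A	G/A	G/A	G/A	G/A	true
1	150808889	rs2228099	ARNT	gtG/gtC	V173	C/G	C/G	C/G	C/G	C/G	true
1	201047062	rs4915476	CACNA1S	Ctg/Ttg	L522	G/A	G/A	A/A	G/A	G/A	false
1	201047075	rs4915477	CACNA1S	ggT/ggC	G517	A/G	G/G	G/G	G/G	G/G	false
1	228402508	rs2776853	OBSCN	Ctg/Ttg	L513	C/T	C/T	C/T	C/T	C/T	true
1	247921100	rs1552812	OR1C1	ggA/ggC	G203	T/G	G/G	G/G	G/G	T/G	false
2	72361960	rs2241057	CYP26B1	tTg/tCg	L189S	A/G	A/G	A/G	A/G	A/G	true
2	100916315	rs11123823	LONRF2	ggT/ggC	G134	G/G	A/G	A/G	G/G	A/G	true
2	100917109	rs13006224	LONRF2	tcG/tcA	S111	T/T	C/T	C/T	T/T	C/T	true
2	101010082	rs3748930	CHST10	acC/acG	T232	C/C	G/C	G/C	C/C	G/C	true
2	101646144	rs3739015	TBC1D8	tcC/tcT	S662	G/A	G/A	G/A	G/A	G/A	true
3	33138544	rs7614776	GLB1	Ttg/Ctg	L12	G/G	G/G	A/G	G/G	G/G	false
3	119133183	rs3732413	ARHGAP31	Ggc/Agc	G803S	G/A	A/A	A/A	A/A	A/A	false
4	76489582	rs2306174	C4orf26	Gtt/Att	V124I	G/A	G/A	G/A	G/A	G/A	true
4	79387442	rs7660664	FRAS1	caC/caT	H2370	C/T	C/T	C/T	C/T	C/T	true
4	159881479	rs9784569	C4orf45	caA/caG	Q105	C/C	C/C	C/C	T/C	T/C	true
6	150067675	rs10872646	NUP43	gTa/gCa	V47A	A/G	A/G	A/G	A/G	A/G	false
6	160952838	rs3124784	LPA	Cgc/Tgc	R2016C	G/A	G/A	G/A	G/A	G/A	true
7	100731829	rs6948536	TRIM56	gcT/gcC	A412	T/C	C/C	T/C	C/C	T/C	false
7	150439500	rs759011	GIMAP5	gcC/gcT	A127	C/T	C/T	T/T	C/T	C/T	true
8	144941181	rs7839934	EPPK1	Ctg/Gtg	L2081V	G/C	G/C	G/C	C/C	G/C	false
9	34729452	rs10115191	RP11-195F19.10	NA	NA	A/G	A/G	A/G	A/G	A/G	false
9	125239253	rs1962091	OR1J1	aAc/aGc	N318S	C/C	C/C	C/C	T/C	T/C	false
10	50532683	rs7921186	C10orf71	tTc/tCc	F698S	C/C	C/C	C/C	C/C	C/C	false
10	70405855	rs3998860	TET1	atA/atG	I1123M	G/G	G/G	G/G	G/G	G/G	false
10	91007360	rs1051338	LIPA	Acc/Ccc	T16P	T/G	T/G	T/G	T/G	T/G	true
11	4790396	rs17324609	OR51F1	gCt/gTt	A251V	A/A	G/A	G/A	A/A	A/A	true
11	4790482	rs12792898	OR51F1	ttA/ttG	L222	C/C	T/C	T/C	C/C	C/C	true
11	4790575	rs12788102	OR51F1	tgT/tgC	C191	G/G	A/G	A/G	G/G	G/G	true
11	4824878	rs2053116	OR52R1	Tcc/Gcc	S245A	C/C	A/C	C/C	C/C	C/C	false
11	4825349	rs17327254	OR52R1	Ttc/Ctc	F167L	G/G	A/G	A/G	G/G	G/G	true
11	4842866	rs35003053	OR51F2	gAc/gGc	D84G	G/G	A/G	A/G	G/G	G/G	true
11	4870284	rs35918613	OR51S1	aCc/aGc	T52S	C/C	G/C	G/C	C/C	C/C	true
11	4944892	rs34583466	OR51G1	acC/acG	T226	C/C	G/C	G/C	C/C	C/C	true
11	4944986	rs12796015	OR51G1	aTt/aCt	I195T	G/G	A/G	A/G	G/G	G/G	true
11	4945199	rs34742470	OR51G1	cGc/cAc	R124H	T/T	C/T	C/T	T/T	T/T	true
11	7949791	rs7933807	OR10A6	gTt/gGt	V140G	A/C	A/C	A/C	C/C	C/C	false
11	12525925	rs11547363	PARVA	cgC/cgT	R149	C/T	C/T	C/T	C/T	C/T	true
11	18422487	rs61736803	LDHA	atC/atA	I116	C/A	C/A	C/A	C/A	C/A	true
11	44940828	rs2291334	TSPAN18	Gtc/Atc	V133I	G/A	G/A	G/A	G/A	G/A	true
11	55872876	rs2512961	OR8H2	Cat/Tat	H120Y	T/T	T/T	T/T	T/T	T/T	false
11	56510623	rs513873	OR9G4	gTa/gCa	V222A	G/G	G/G	A/G	A/G	A/G	true
11	56510694	rs1397053	OR9G4	ccA/ccG	P198	T/C	T/C	T/C	T/C	T/C	true
11	74862391	rs1944612	SLCO2B1	NA	NA	G/G	G/G	G/G	G/G	G/G	false
11	108175462	rs1801516	ATM	Gat/Aat	D1853N	G/A	G/A	G/A	G/A	G/A	true
11	117266312	rs2305830	CEP164	aCc/aGc	T962S	C/G	C/G	C/G	C/G	C/G	false
12	109693982	rs3742023	ACACB	caC/caT	H1299	T/T	C/T	C/T	C/T	C/T	false
13	46946157	rs1408184	KIAA0226L	Ggg/Agg	G152R	T/T	C/T	C/T	C/T	C/T	false
13	49776080	rs9316430	FNDC3A	aaA/aaG	K1044	A/G	A/G	A/G	A/G	A/G	true
14	64637147	rs7161192	SYNE2	ctC/ctA	L2119	C/A	A/A	C/A	C/A	C/A	false
15	58838038	rs6084	LIPC	acC/acG	T163	C/G	G/G	C/G	G/G	C/G	true
15	78390909	rs12593575	SH2D7	Cgg/Tgg	R206W	C/T	C/T	C/T	C/T	C/T	false
16	2812890	rs2240141	SRRM2	aaA/aaG	K39	G/G	G/G	A/G	G/G	G/G	false
16	3490922	rs2270494	ZNF597	ctC/ctG	L15	G/C	C/C	G/C	C/C	G/C	false
18	59936142	rs17645999	KIAA1468	gtC/gtT	V907	T/T	C/T	T/T	C/T	C/T	true
19	2917612	rs10410539	ZNF57	acT/acC	T299	C/C	C/C	T/C	T/C	T/C	false
19	18679379	rs7648	C19orf50	Cct/Gct	P157A	C/G	G/G	G/G	G/G	G/G	false
19	20748522	rs12979592	ZNF737	NA	NA	C/A	C/A	C/A	C/A	C/A	true
19	34959979	rs7259160	UBA2	tcA/tcG	S496	A/G	G/G	G/G	A/G	G/G	false
20	13134768	rs6078938	SPTLC3	taT/taC	Y466	C/C	T/C	T/C	T/C	T/C	true
20	55108617	rs3209183	C20orf107	Cag/Aag	Q74K	A/A	A/A	C/A	C/A	C/A	false
21	33887131	rs1129157	C21orf63	ccG/ccA	P271	G/A	G/A	G/A	G/A	A/A	true
22	18209920	rs9306198	BCL2L13	Cct/Tct	P198S	T/T	C/T	C/T	C/T	C/T	true
22	32554985	rs5998267	C22orf42	cTg/cCg	L73P	G/G	A/G	A/G	A/G	A/G	false
X	13337059	rs4830842	ATXN3L	gGc/gAc	G332D	C/T	C/T	C/T	T/T	C/T	true
X	55514818	rs3126255	USP51	gaG/gaA	E185	C/T	C/T	C/T	T/T	T/T	false
X	70146398	rs4360450	SLC7A3	agT/agC	S533	A/G	G/G	A/G	G/G	G/G	false
X	74494470	rs4892396	UPRT	cgT/cgG	R127	G/G	G/G	G/G	G/G	G/G	false
X	85219021	rs10217950	CHM	gcA/gcG	A117	T/C	T/C	T/C	C/C	C/C	false
X	88008807	rs5984611	CPXCR1	cGt/cAt	R131H	G/A	G/A	G/A	G/A	G/A	false
X	105153001	rs209372	NRK	aaA/aaG	K456	G/G	G/G	G/G	G/G	G/G	false
X	107417730	rs5973851	COL4A6	ggC/ggT	G1026	G/A	G/A	G/A	G/A	G/A	true
X	114425400	rs12857270	RBMXL3	Gga/Aga	G466R	A/A	G/A	A/A	A/A	A/A	false
X	117700141	rs2286977	DOCK11	gcA/gcG	A289	A/G	A/G	G/G	A/G	A/G	false
X	118604436	rs12390	SLC25A5	acT/acC	T233	C/C	C/C	T/C	T/C	C/C	false
X	118699320	rs5910616	CXorf56	NA	NA	G/G	G/G	A/G	G/G	G/G	false
X	133379551	rs2428577	CCDC160	Cta/Tta	L241	T/T	T/T	T/T	T/T	T/T	false
X	142967468	rs237520	UBE2NL	tTa/tGa	L89*	T/G	T/G	T/G	G/G	G/G	true
X	144904882	rs2748588	SLITRK2	ccT/ccC	P313	T/C	C/C	C/C	C/C	C/C	false
X	153633359	rs1130929	DNASE1L1	ccC/ccG	P67	C/C	C/C	C/C	C/C	C/C	false
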