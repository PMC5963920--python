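Chr	Position	Gene	cDNA variant	Protein variant
1	33476435	AK2	c.*45-1G>T	
1	36752343	THRAP3	c.512C>T	p.Ser171Phe
1	36932102	CSF3R	c.2273C>T	p.Thr758Ile
1	39758439	MACF1	c.1931G>T	p.Gly644Val
1	145365316	NBPF10	c.9941G>A	p.Gly3314Glu
2	11758842	GREB1	c.3841G>A	p.Ala1281Thr
2	29404617	CLIP4	c.1976G>A	p.Arg659Gln
2	64779195	AFTPH	c.587G>A	p.Gly196Glu
2	238277211	COL6A3	c.4895G>A	p.Arg1632Gln
2	241987827	SNED1	c.1369G>A	p.Glu457Lys
3	38348802	SLC22A14	c.574G>A	p.Ala192Thr
3	44672687	ZNF197	c.524C>T	p.Ala175Val
3	47452772	PTPN23	c.3484C>T	p.Arg1162Trp
3	52556184	STAB1	c.6403C>G	p.Pro2135Ala
3	67426232	SUCLG2	c.1235T>C	p.Ile412Thr
3	197422844	KIAA0226	c.1366C>T	p.Arg456Trp
4	9174981	FAM90A26P	c.83T>G	p.Val28Gly
4	9175603	FAM90A26P	c.211C>G	p.Pro71Ala
4	10089539	WDR1	c.743A>G	p.His248Arg
4	15529151	CC2D2A	c.1231T>G	p.Ser411Ala
5	74021852	GFM2	c.1820_1825delTTGAGT	p.Glu608_Phe609del
5	78610479	JMY	c.2464C>A	p.Pro822Thr
5	149602589	CAMK2A	c.1429C>T	p.His477Tyr
5	154199950	C5orf4	c.928G>A	p.Glu310Lys
5	156456715	HAVCR1	c.1090G>A	p.Ala364Thr
5	156479452	HAVCR1	c.590_592delCAA	p.Thr198del
6	26509392	BTN1A1	c.1571G>A	p.Gly524Glu
6	27215709	PRSS16	c.119G>A	p.Ser40Asn
6	32806007	TAP2	c.4C>T	p.Arg2Trp
6	33260924	RGL2	c.1876G>A	p.Gly626Arg
6	38704952	DNAH8	c.221C>A	p.Ala74Asp
6	43412643	ABCC10	c.2807C>T	p.Pro936Leu
6	129932746	ARHGAP18	c.1054C>T	p.Arg352Ter
6	131946054	MED23	c.235C>T	p.Leu79Phe
6	151674121	AKAP12	c.4595_4596insGGC	p.Asp1532delinsGluAla
6	168479677	FRMD1	c.98A>C	p.Glu33Ala
7	5352665	TNRC18	c.7851_7856dupCTCCTC	p.Ser2618_Ser2619dup
7	45123857	NACAD	c.1922T>C	p.Val641Ala
7	143884437	ARHGEF35	c.1040C>T	p.Thr347Ile
7	149422981	KRBA1	c.1304C>T	p.Ala435Val
7	151680130	GALNTL5	c.428A>G	p.Tyr143Cys
8	12285064	FAM86B1|FAM86B2	c.310T>C	p.Ser104Pro
8	12285250	FAM86B2	c.808C>T	p.Arg270Trp
8	86574132	REXO1L1	c.1595A>C	p.Asp532Ala
9	12775863	LURAP1L	c.149_150insTGGCGG	p.Gly49_Gly50dup
9	40706047	FAM75A3	c.3704A>G	p.His1235Arg
9	41323425	FAM75A4	c.1908C>T	p.Arg637Trp
9	41323469	FAM75A4	c.1864G>A	p.Gly622Asp
9	43822668	CNTNAP3B	c.1222C>T	p.Leu408Phe
10	51748684	AGAP6	c.209G>A	p.Arg70Gln
10	81471741	FAM22B	c.2137T>C	p.Trp713Arg
11	1651198	KRTAP5-5	c.129_137delAGGCTGTGG	p.Gly44_Gly46del
11	12316388	MICALCL	c.1408_1410dupCCT	p.Pro470dup
12	7045917	ATN1	c.1488_1508delGCAGCAGCAGCAGCAGCAGCA	p.Gln496_Gln502del
12	7045920	ATN1	c.1491_1508delGCAGCAGCAGCAGCAGCA	p.Gln497_Gln502del
13	99461564	DOCK9	c.1271_1272insA	p.Leu425LeufsTer?
13	114503875	FAM70B	c.500_509+72delCCTGCGGGAGGTGAGGGGCACCGGGGACCCCCATATCTACACCTGCGGGAGGTGAGGGGCGCTGGGGACCCCCGTATCTACA	
14	105411514	AHNAK2	c.10274C>T	p.Ala3425Val
14	106994118	IGHV3-48	c.47G>A	p.Gly16Asp
16	29496359		c.916T>C	p.Ser306Pro
16	30772988	C16orf93	c.82G>A	p.Ala28Thr
16	70215817	CLEC18C	c.521C>T	p.Ala174Val
17	39211189	KRTAP2-2	c.275G>C	p.Cys92Ser
19	1026716	CNN2	c.56A>C	p.Lys19Thr
19	10084460	COL5A3	c.3584T>C	p.Val1195Ala
19	14517213	CD97	c.1892G>A	p.Ser631Asn
21	36042462	CLIC6	c.776_805delGCGTAGAAGCGGGGGTCCCGGCGGGGGACA	p.Val260_Ser269del
22	18834773		c.329C>T	p.Thr110Ile
X	48920059	CCDC120	c.110A>G	p.Asp37Gly
X	55116478	PAGE2	c.25T>A	p.Ser9Thr
X	150832702	PASD1	c.954_971delCCCAATGGACCAGCAGGA	p.Pro319_Asp324del
X	153050158	SRPK3	c.1_5delGACAG	p.Thr2LeufsTer57
X	154010046	MPP1	c.978A>C	p.Glu326Asp
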