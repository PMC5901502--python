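gene	chrom	pos	id	ancestral	derived	in_imms
RERE	1	8419873	rs376434590	T	C	NO
RERE	1	8419874	novel	T	G	NO
RERE	1	8421203	rs13596	T	C	NO
BRINP2	1	177247854	rs31764431	C	G	NO
CYP26B1	2	72361960	rs2241057	A	G	NO
MARS2	2	198570253	rs200490327	G	A	NO
GIGYF2	2	233712227	rs7563724	A	G	NO
STAB1	3	52546872	rs150311081	G	A	NO
STAB1	3	52548136	rs74491782	T	C	NO
PBRM1	3	52643685	rs3755806	T	C	NO
ITIH4	3	52850999	rs2535621	A	G	NO
ITIH4	3	52863155	rs150181495	G	A	NO
MUSTN1	3	52867718	rs2276820	C	T	NO
ATXN7	3	63982082	rs3774729	G	A	NO
KDM3B	5	137754695	rs7726234	T	C	NO
DND1	5	140052271	rs2563333	A	G	NO
PCDHA1	5	140168070	rs2240696	A	G	NO
PCDHA3	5	140182101	rs7701755	G	T	NO
PCDHA4	5	140188383	rs2337987	T	G	NO
PCDHA4	5	140188401	rs2879086	A	G	NO
PCDHA8	5	140221139	rs3756331	G	A	NO
PCDHA8	5	140221195	rs199713478	G	C	NO
GPX5	6	28497245	novel	C	T	NO
GPX5	6	28497279	rs60523386	G	A	NO
SCAND3	6	28541036	novel	C	T	NO
SCAND3	6	28543089	rs41270593	G	T	NO
SRPK2	7	104782888	rs2240464	A	T	YES
SRPK2	7	104844229	rs56318802	C	T	YES
DGKZ	11	46387868	rs1317826	A	G	NO
DGKZ	11	46393138	novel	C	T	NO
F2	11	46747662	rs5899	C	T	YES
ZDHHC5	11	57463496	rs140343860	C	T	NO
ZDHHC5	11	57466653	novel	G	A	NO
STAT6	12	57499258	rs118014438	C	T	YES
LRP1	12	57548364	rs34574998	T	C	NO
LRP1	12	57575070	rs199672493	C	T	NO
LRP1	12	57592090	rs370217380	G	A	NO
NXPH4	12	57619362	rs10783816	G	A	NO
PITPNM2	12	123480138	novel	C	T	NO
CDK2AP1	12	123749780	rs150530930	G	A	NO
XRCC3	14	104165239	novel	G	A	NO
XRCC3	14	104169630	rs138987760	C	T	NO
PLCB2	15	40590134	rs2229690	G	A	NO
PLCB2	15	40594191	rs373064934	A	G	NO
ADAMTSL3	15	84706461	rs950169	C	T	NO
FES	15	91428302	rs377657111	C	T	YES
THAP11	16	67876823	rs28647874	A	G	NO
THAP11	16	67876826	rs3982383	G	A	NO
THAP11	16	67876835	rs151159352	G	A	NO
THAP11	16	67876844	novel	G	A	NO
CTRL	16	67964203	rs1134760	T	C	NO
PSMB10	16	67969531	rs14178	A	G	YES
SLC12A4	16	67979051	rs373093291	G	A	NO
SLC12A4	16	67980969	rs11860125	G	C	NO
PLA2G15	16	68293320	rs3743739	T	C	NO
SMG6	17	2203025	rs1885987	T	G	NO
SMG6	17	2203356	rs35172468	C	G	NO
GID4	17	17948475	rs2955355	G	A	NO
MYO15A	17	18022235	rs200234990	C	T	NO
MYO15A	17	18023897	rs2955365	G	A	NO
TSSK6	19	19625547	rs7250893	A	G	NO
ZNF536	19	31038940	rs199936097	G	A	NO
ZNF536	19	31038995	rs1469705	T	C	NO
ACTR5	20	37377139	rs2254105	C	T	NO
L3MBTL2	22	41610024	rs139451	G	A	NO
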