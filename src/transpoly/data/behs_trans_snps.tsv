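gene	id	avg_het	het_se	func_class	fst	tajimas_d	phenotype_note	denisova_het
ALS2	rs3219156	0.185	0.240	missense	0.1642	-0.558111591	Amyotrophic lateral sclerosis/parkinsonism-dementia complex	NO
ALS2	rs3219168	0.158	0.233	synonymous	0.1191	-0.093457107	Amyotrophic lateral sclerosis	NO
ANK2	rs33966911	0.104	0.203	synonymous	0.1239	-0.750076422	NA	NO
ANKRD11	rs72821356	0.058	0.160	synonymous	0.0255	-0.931794107	KBG syndrome (OMIM 611192)	NO
ANKRD11	rs60520302	0.072	0.176	missense	0.0019	-0.931794107	KBG syndrome (OMIM 611192)	NO
APOL2	rs118097350	0.006	0.054	missense	0.0005	0.301905912	NA	NO
BCL11A	rs7569946	0.282	0.248	synonymous	0.0742	-0.928248907	Fetal Hemoglobin Level	NO
CACNA2D3	rs17054785	0.181	0.240	synonymous	0.0766	-0.12464999	NA	NO
CCDC108	rs13403802	0.028	0.115	missense	0.0467	-0.365570142	NA	NO
CHD1	rs161941	0.417	0.186	synonymous	0.3542	-0.774153927	NA	NO
CHI3L1	rs140857184	0.013	0.080	missense	0.0346	-0.860993564	NA	NO
CHL1	rs116261368	0.028	0.115	missense	0.0409	-0.478853152	NA	NO
CHL1	rs2272522	0.428	0.175	missense	0.133	-0.478853152	Schizophrenia	NO
CTNS	rs161400	0.269	0.249	missense	0.6469	0.188849119	Nephropatic cystinosis	NO
CTNS	rs77453839	0.130	0.219	synonymous	0.2947	0.383526916	Nephropatic cystinosis	NO
DBH	rs1108580	0.490	0.069	synonymous	0.2628	0.111473168	Schizophrenia, TDAH, cocaine dependence, fetal growth, bipolar disorder	NO
DISC1	rs55795950	0.004	0.042	missense	0.0094	-0.209468866	Schizophrenia	NO
DRD5	rs184288806	0.002	0.032	synonymous	NA	NA	NA	NO
EEF1A2	rs310617	0.483	0.090	synonymous	0.0102	0.516242391	Mental retardation, Epilectic encephalopathy (OMIM 602959)	YES
EIF4EBP2	rs3750767	0.029	0.117	synonymous	0.0332	-0.133346514	NA	NO
GPR153	rs140518856	0.005	0.049	synonymous	NA	NA	NA	NO
GRM5	rs2306153	0.091	0.193	synonymous	0.0516	-0.65655565	NA	NO
HOXB8	rs45441492	0.114	0.210	synonymous	0.1385	-0.957471816	NA	NO
HRAS	rs12628	0.418	0.185	synonymous	0.0217	-0.20012551	Costello syndrome	NO
HTT	rs363125	0.307	0.243	missense	0.3302	-0.83813619	Huntington disease (OMIM 613004)	NO
HTT	rs362331	0.493	0.058	missense	0.0336	-0.718349527	Huntington disease (OMIM 613004)	NO
HTT	rs140124504	0.002	0.032	synonymous	NA	NA	Huntington disease (OMIM 613004)	NO
HTT	rs138489139	0.002	0.035	synonymous	NA	NA	Huntington disease (OMIM 613004)	NO
KDM6B	rs11078709	0.490	0.070	synonymous	0.3901	-1.068036831	NA	NO
KLF12	rs77377545	0.019	0.096	synonymous	0.026	-0.747818207	Panic disorder syndrome 1 (OMIM 167870)	NO
LRRK2	rs11176013	0.485	0.084	synonymous	0.0246	0.777713125	Parkinson disease 8 (OMIM 609007)	NO
LRRTM1	rs6733871	0.465	0.128	missense	0.1323	-1.03399393	Schizophrenia	NO
MC4R	rs2229616	0.032	0.122	missense	0.01	-1.339833048	Obesity	NO
MKKS	rs17852625	0.310	0.243	synonymous	0.0393	0.147132768	Obesity	NO
MKKS	rs16991547	0.363	0.223	synonymous	0.1067	0.147132768	NA	NO
NMUR2	rs4958532	0.215	0.248	missense	0.1464	-0.701022375	NA	NO
OR4C46	rs11246606	0.363	0.223	missense	-0.0025	-1.30558338	NA	NO
PAK7	rs55773719	0.013	0.081	synonymous	0.0145	-0.339650099	NA	NO
PHF2	rs56134753	0.040	0.135	synonymous	0.0199	-0.264535787	NA	NO
PLCL2	rs7653834	0.496	0.047	synonymous	0.054	-0.63849307	NA	NO
PRODH	rs139903009	0.004	0.047	missense	0.0005	0.292869235	Schizophrenia (OMIM 606810)	NO
PRODH	rs4819756	0.342	0.232	missense	0.3182	0.309595729	Schizophrenia	NO
PRODH	rs1808320	0.393	0.205	synonymous	0.1409	0.369538366	Autism, Schizophrenia	NO
RGS12	rs80251844	0.088	0.191	missense	0.1524	-0.829372734	NA	NO
RGS12	rs147416450	0.002	0.028	missense	NA	NA	NA	NO
RIMS1	rs77121218	0.019	0.097	synonymous	0.0092	-1.576071446	Cone-rod dystrophy (OMIM 606629)	YES
SCN9A	rs4369876	0.064	0.167	missense	0.0735	-0.16967483	Basal Pain Sensitivity	NO
SHANK1	rs3745521	0.405	0.196	missense	0.2752	-0.048981111	Specific language impairment (OMIM 606712); Mental retardation (OMIM 611097)	NO
TCF3	rs11882821	0.033	0.123	synonymous	0.0467	-1.767706279	NA	NO
TEKT5	rs148185751	0.005	0.051	missense	0.0005	0.183653042	NA	NO
THBS4	rs438042	0.490	0.069	synonymous	0.0334	0.252034645	Alzheimer Disease	NO
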