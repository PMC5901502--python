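percentile	imms_snps	imms_trans_snps_nonsyn	imms_trans_snps	behs_snps	behs_trans_snps_nonsyn	behs_trans_snps
5	0.769932	0.083713	0.166287	0.988971	0.099265	0.209559
10	0.777335	0.086560	0.170273	1.007350	0.106618	0.220588
15	0.782375	0.088838	0.173121	1.022060	0.110294	0.227941
20	0.786446	0.090547	0.175399	1.036760	0.113971	0.235294
25	0.789863	0.091686	0.177677	1.044120	0.117647	0.238971
30	0.792711	0.093394	0.179385	1.055150	0.121324	0.246324
35	0.796128	0.094533	0.181093	1.062500	0.125000	0.250000
40	0.798405	0.095672	0.182802	1.069850	0.128676	0.253676
45	0.801253	0.096811	0.184510	1.077210	0.132353	0.257353
50	0.804100	0.097950	0.185649	1.084560	0.132353	0.261029
55	0.806378	0.098519	0.187358	1.091910	0.136029	0.264706
60	0.809226	0.099658	0.188497	1.099260	0.139706	0.272059
65	0.811503	0.100797	0.190205	1.110290	0.143382	0.275735
70	0.814351	0.101936	0.191913	1.117650	0.147059	0.279412
75	0.817768	0.103645	0.194191	1.125000	0.150735	0.286765
80	0.821185	0.105353	0.196469	1.136030	0.154412	0.290441
85	0.825171	0.106492	0.198178	1.147060	0.158088	0.297794
90	0.830296	0.109339	0.201025	1.161760	0.165441	0.308824
95	0.838269	0.112187	0.206150	1.187500	0.172794	0.319853
100	0.882688	0.133827	0.231207	1.327210	0.227941	0.400735
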