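region	type	from	to	known_cluster	known_cluster_type	similarity	technique
1.1	T1PKS	173,653	262,468	catenulisporolides	NRP + Polyketide	12%	Illumina
1.2	T3PKS	972,718	1,013,770	loseolamycin A1/loseolamycin A2	Polyketide	92%/88%	Both
1.3	thioamide-NRP	1,165,443	1,214,791	cadaside A/cadaside B	NRP	19%	Illumina
1.4	terpene	1,632,755	1,652,207	isorenieratene	Terpene	25%/25%	Both
1.5	terpene	1,735,876	1,756,185	phosphonoglycans	Saccharide	3%	Illumina
1.9	T1PKS	3,818,978	3,889,418	quinolidomicin A	Polyketide	45%/67%	Both
1.10	NI-siderophore	3,941,102	3,951,331	FW0622	Other	50%	Illumina
1.11	NRPS-like,NRPS,T1PKS,PKS-like	3,956,633	4,058,605	sungeidine C/sungeidine B/sungeidine D/sungeidine H/sungeidine A/sungeidine E/sungeidine F/sungeidine G	Polyketide	100%	Illumina
1.12	NRPS-like,NRPS,T1PKS	4,153,951	4,219,351	crochelin A	NRP + Polyketide	12%	Illumina
1.13	terpene	4,832,538	4,853,269	nocathiacin	RiPP:Thiopeptide	4%/4%	Both
1.14	T2PKS	5,027,025	5,098,322	formicamycins A-M	Polyketide	18%	Illumina
1.15	oligosaccharide, terpene	5,268,386	5,304,696	lobosamide A/lobosamide B/lobosamide C	Polyketide	13%	Illumina
1.16	T2PKS,oligosaccharide, other,NRPS	5,309,290	5,436,713	cinerubin B	Polyketide:Type II polyketide	80%/74%	Both
1.17	NI-siderophore	5,616,661	5,629,872	peucechelin	NRP	10%	Illumina
1.18	terpene,RiPP-like	5,837,876	5,861,979	lymphostin/neolymphostinol B/lymphostinol/neolymphostin B	NRP + Polyketide	33%	Illumina
1.19	terpene	5,994,482	6,015,432	tetrachlorizine	Polyketide	13%	Illumina
1.20	other, ladderane,NRPS, arylpolyene	6,201,575	6,311,984	kedarcidin	NRP + Polyketide:Iterative type I polyketide + Polyketide:Enediyne type I polyketide	13%/6%	Both
6.1	NRPS-like,T1PKS	1	37,77	quinolidomicin A	Polyketide	28,%/67%	Both
2.1	RiPP-like	136,664	147,482	lymphostin/neolymphostinol B/lymphostinol/neolymphostin b	Polyketide + NRP	15%	MinION
2.5	NI-siderophore	4,182,055	4,194,725	peucechelin	NRP	10%	MinION
3.2	NRPS-like	407,718	448,468	sarpeptin A/sarpeptin B	NRP	25%	MinION
3.4	oligosaccharide, terpene	530,94	565,187	brasilicardin A	Terpene + Saccharide	38%	MinION
3.5	T2PKS,NRPS-like	732,357	804,659	pradimicin-A	Polyketide	17%	MinION
3.7	NRPS	1,520,332	1,559,968	bleomycin A2/bleomycin B2	NRP + Polyketide + Saccharide	14%	MinION
3.9	T1PKS	1,799,831	1,841,948	rakicidin A/rakicidin B	NRP:Cyclic depsipeptide + Polyketide:Modular type I polyketide	40%	MinION
3.10	NI-siderophore	1,859,147	1,870,220	putrebactin/avaroferrin	Other	50%	MinION
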