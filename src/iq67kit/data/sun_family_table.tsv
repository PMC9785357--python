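name	gene_id	chromosome	orf_bp	aa	mw_kd	pi
CmSUN1-2a	MELO3C014258.2.1	Chrom05	1473	490	53.7	9.87
CmSUN1-2b	MELO3C009321.2.1	Chrom04	1491	496	56.4	10.34
CmSUN3	MELO3C025505.2.1	Chrom09	1449	482	53.4	10.42
CmSUN4	MELO3C012442.2.1	Chrom10	1395	464	52.1	10.06
CmSUN5	MELO3C009991.2.1	Chrom02	1302	433	48.5	10.22
CmSUN6	MELO3C016880.2.1	Chrom07	1338	445	49.6	10.47
CmSUN7-8	MELO3C024381.2.1	Chrom01	1221	406	45.8	10.26
CmSUN9-10a	MELO3C016091.2.1	Chrom07	786	261	29.9	10.04
CmSUN9-10b	MELO3C007235.2.1	Chrom08	1107	368	41.9	10.31
CmSUN11	MELO3C005137.2.1	Chrom09	1440	479	54.1	10.02
CmSUN13-14a	MELO3C022423.2.1	Chrom11	1614	537	60.5	10.87
CmSUN13-14b	MELO3C017768.2.1	Chrom07	1650	549	61.4	10.47
CmSUN17-18a	MELO3C022253.2.1	Chrom11	1539	512	57.5	10.42
CmSUN19a	MELO3C014290.2.1	Chrom05	1452	483	53.8	9.63
CmSUN19b	MELO3C006504.2.1	Chrom06	1269	422	46.9	9.81
CmSUN19c	MELO3C004368.2.1	Chrom05	1128	375	43.4	9.98
CmSUN21a	MELO3C008499.2.1	Chrom06	1410	469	52.8	9.60
CmSUN21b	MELO3C005888.2.1	Chrom09	1125	374	41.8	9.96
CmSUN23-24	MELO3C006884.2.1	Chrom06	1413	470	51.5	10.28
CmSUN25-26-27a	MELO3C015418.2.1	Chrom02	1233	410	45.4	10.25
CmSUN25-26-27b	MELO3C024434.2.1	Chrom01	1293	430	48.3	9.66
CmSUN25-26-27c	MELO3C013004.2.1	Chrom04	1161	386	42.8	10.29
CmSUN30-31	MELO3C002201.2.1	Chrom12	1800	599	65.9	9.80
CmSUN32b	MELO3C010997.2.1	Chrom03	2538	845	93.4	5.59
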