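id	sequence	design_cycles	rosetta_score	time_bound_ns	censored	dg_mmgbsa	dg_mmgbsa_sem	dg_rigorous	dg_rigorous_unc
T0	CIIHHKKPTGMIRIHQM	0	172.4	61.3	0	-12.6	0.3
T1	CIIHHKKPTGMIRIHQM	0	173.6	58.3	0	-16.4	0.5
T2	CIIHHKKPTGMIRIHQM	0	170.8	90.8	0	-12.2	0.2
1	ECRYEPRPEGNILVSYS	1	170.6	660.2	0	-22.7	0.2
2	SIVTKLTPTGWVAASYS	1	175.1	899.4	0	-26.4	0.1
3	KVEFKRTPSGTITVSME	1	165.8	12.8	0	-10.4	0.6
4	KVVYEPKPEGNIVVEYE	1	194.3	48.4	0	-12.4	0.3
5	SAKFEPRPEGNIVVSYG	2	200.6	134.0	0	-22.7	0.2
6	EARYQPRPDGNVLVSYG	2	206.0	245.0	0	-14.2	0.2
7	SAKWNPKPEGAELIEEG	2	222.8	16.0	0	-7.7	0.7
8	SAEFIPTPDGNLLKSSG	2	214.0	13.8	0	-8.8	0.7
9	SIVVVLTPTGWVAASYS	2	157.6	278.0	0	-26.9	0.3
10	EIITKLTPTGWVAASYS	2	157.6	86.2	0	-19.3	0.4
11	SIEMELTPTGWVNKSSS	2	157.9	44.2	0	-11.3	0.3
12	SIITVLTPTGWVAAEFS	2	155.7	1110.6	0	-32.8	0.1	-10.2	2.4
13	DIITILTPTGYVAAAYS	3	154.0	395.6	0	-19.0	0.2
14	SIITVLTPTGWVAAYYS	3	155.3	1463.2	0	-23.3	0.1
15	SIQCVLTPTGWVAARYS	3	155.1	42.4	0	-20.3	0.7
16	EIDTVLTPTGWVAKRYS	3	153.8	2000.0	1	-22.3	0.1	-6.6	3.5
17	SIRMELTPTGWVAAEYE	3	165.2	119.4	0	-18.5	0.4
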