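taxon_group	guild	higher_group	n_specimens	n_larva	n_pupa	n_adult	n_morphospecies	n_bins	pct_family	pct_subfamily	pct_genus	pct_species
Agathidinae	parasitoid	B	1	1	0	0	1	1	100.0	100.0	100.0	0.0
Anomaloninae	parasitoid	I	1	0	0	1	1	1	100.0	100.0	100.0	100.0
Banchinae	parasitoid	I	5	0	0	5	5	4	100.0	50.0	50.0	25.0
Campopleginae	parasitoid	I	80	1	3	76	17	15	100.0	60.0	53.3	33.3
Cryptinae	parasitoid	I	4	0	0	4	3	3	100.0	66.7	66.7	66.7
Entedoninae	parasitoid	CH	2	0	0	2	1	1	100.0	0.0	0.0	0.0
Eulophinae	parasitoid	CH	104	1	3	100	6	14	92.9	64.3	64.3	14.3
Euphorinae	parasitoid	B	3	0	3	0	1	1	100.0	100.0	100.0	100.0
Homolobinae	parasitoid	B	1	0	0	1	1	1	100.0	100.0	0.0	0.0
Hormiinae	parasitoid	B	1	0	0	1	1	1	100.0	100.0	0.0	0.0
Macrocentrinae	parasitoid	B	7	0	0	7	2	2	100.0	100.0	100.0	0.0
Mesochorinae	parasitoid	I	13	0	1	12	6	5	100.0	40.0	20.0	20.0
Microgastrinae	parasitoid	B	96	0	20	76	19	26	96.2	96.2	53.8	26.9
Ophioninae	parasitoid	I	8	4	3	1	3	3	66.7	66.7	66.7	66.7
Orgilinae	parasitoid	B	2	0	0	2	1	1	100.0	100.0	0.0	0.0
Perilampinae	parasitoid	CH	6	0	6	0	1	1	0.0	0.0	0.0	0.0
Pimplinae	parasitoid	I	1	0	0	1	1	1	100.0	100.0	100.0	100.0
Pteromalinae	parasitoid	CH	1	0	1	0	1	1	100.0	0.0	0.0	0.0
Rogadinae	parasitoid	B	16	0	2	14	1	2	100.0	100.0	100.0	100.0
Tryphoninae	parasitoid	I	1	1	0	0	1	1	100.0	100.0	100.0	100.0
Dexiinae	parasitoid	T	5	0	5	0	2	2	100.0	50.0	50.0	50.0
Exoristinae	parasitoid	T	86	1	78	7	10	12	100.0	91.7	91.7	91.7
Tachininae	parasitoid	T	18	0	13	5	4	3	100.0	100.0	100.0	100.0
other	parasitoid		3	2	1	0	2	2	0.0	0.0	0.0	0.0
Argidae	host	H	1	1	0	0	1	1	100.0	100.0	100.0	100.0
Bucculatricidae	host	L	10	8	0	2	3	3	100.0	100.0	100.0	66.7
Depressariidae	host	L	2	2	0	0	1	1	100.0	100.0	100.0	100.0
Drepanidae	host	L	2	2	0	0	1	1	100.0	100.0	100.0	100.0
Erebidae	host	L	26	22	1	3	6	7	100.0	100.0	100.0	100.0
Gelechiidae	host	L	6	6	0	0	6	6	100.0	100.0	83.3	83.3
Geometridae	host	L	145	99	37	9	29	34	100.0	100.0	97.1	88.2
Gracillariidae	host	L	4	4	0	0	3	3	100.0	100.0	100.0	66.7
Limacodidae	host	L	1	0	1	0	1	1	100.0	100.0	100.0	100.0
Lypusidae	host	L	20	20	0	0	3	3	100.0	100.0	100.0	66.7
Noctuidae	host	L	41	33	6	2	14	13	100.0	100.0	100.0	92.3
Nolidae	host	L	11	10	1	0	3	3	100.0	100.0	100.0	100.0
Notodontidae	host	L	8	8	0	0	5	5	100.0	100.0	100.0	100.0
Psychidae	host	L	15	11	3	1	4	6	100.0	100.0	100.0	83.3
Pyralidae	host	L	1	1	0	0	1	1	100.0	100.0	100.0	100.0
Roeslerstammiidae	host	L	2	2	0	0	2	2	100.0	100.0	100.0	100.0
Tenthredinidae	host	H	6	5	1	0	3	3	100.0	100.0	100.0	100.0
Tortricidae	host	L	26	16	4	6	8	12	100.0	100.0	100.0	100.0
Ypsolophidae	host	L	3	2	0	1	3	3	100.0	100.0	100.0	100.0
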