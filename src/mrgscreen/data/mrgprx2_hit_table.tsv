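compound_id	name	pubchem_cid	indication	drug_class	approval_status	b_score_wt	b_score_mut	pct_change
CID56205	Difloxacin Hydrochloride	56205	Antibiotics (Fluoroquinolone)	Antibiotics (Fluoroquinolone)	INN	44.81	-1.54	-103.45
CID149096	Levofloxacin	149096	Antibiotics (Fluoroquinolone)	Antibiotics (Fluoroquinolone)	FDA	39.73	-0.74	-101.85
CID4539	Norfloxacin	4539	Antibiotics (Fluoroquinolone)	Antibiotics (Fluoroquinolone)	FDA	28.07	0.05	-99.81
CID60062	Clinafoxacin Hydrochloride	60062	Antibiotics (Fluoroquinolone)	Antibiotics (Fluoroquinolone)	USAN, INN	26.08	0.92	-96.48
CID176015	Rufloxacin Hydrochloride	176015	Antibiotics (Fluoroquinolone)	Antibiotics (Fluoroquinolone)	INN, BAN	19.85	-0.15	-100.76
CID102678	Alexidine Hydrochloride	102678	Antibiotics (Non-Fluoroquinolone)	Antibiotics (Non-Fluoroquinolone)	USAN, INN	30.77	1.68	-94.54
CID10909430	Bacitracin A	10909430	Antibiotics (Non-Fluoroquinolone)	Antibiotics (Non-Fluoroquinolone)	FDA	20.22	-0.17	-100.82
CID135398735	Rifampin	135398735	Antibiotics (Antitubercular)	Antibiotics (Non-Fluoroquinolone)	FDA	23.94	0.37	-98.45
CID3386	Fluoxetine	3386	Antidepressive Agents (Second-Generation)	Antidepressive/Antipsychotic Agents	FDA	36.30	7.14	-80.32
CID8228	Imipramine Hydrochloride	8228	Antidepressive Agents (Tricyclic)	Antidepressive/Antipsychotic Agents	FDA	32.17	16.90	-47.47
CID68539	Clomipramine Hydrochloride	68539	Antidepressive Agents (Tricyclic)	Antidepressive/Antipsychotic Agents	FDA	30.29	2.17	-92.83
CID9419	Dibenzepin	9419	Antidepressive Agents (Tricyclic)	Antidepressive/Antipsychotic Agents	INN, BAN	25.48	-1.62	-106.37
CID4976	Protriptyline Hydrochloride	4976	Antidepressive Agents (Tricyclic)	Antidepressive/Antipsychotic Agents	FDA	24.43	3.59	-85.30
CID5282318	Trimipramine Maleate	5282318	Antidepressive Agents (Tricyclic)	Antidepressive/Antipsychotic Agents	FDA	23.09	3.48	-84.91
CID5887	Promazine Hydrochloride	5887	Antipsychotic Agents	Antidepressive/Antipsychotic Agents	FDA	23.47	8.13	-65.37
CID941651	Thiothixene	941651	Antipsychotic Agents	Antidepressive/Antipsychotic Agents	FDA	20.36	5.11	-74.90
CID13770	Cyproheptadine Hydrochloride	13770	Anti-Allergic Agents (Histamine H1 Antagonist)	Anti-Allergic Agents	FDA	41.66	2.29	-94.50
CID5281067	Brompheniramine Maleate	5281067	Anti-Allergic Agents (Histamine H1 Antagonist)	Anti-Allergic Agents	FDA	41.41	1.21	-97.07
CID5282409	Carbinoxamine Maleate	5282409	Anti-Allergic Agents (Histamine H1 Antagonist)	Anti-Allergic Agents	FDA	38.93	1.49	-96.18
CID54360	Azelastine Hydrochloride	54360	Anti-Allergic Agents (Histamine H1 Antagonist)	Anti-Allergic Agents	FDA	36.21	3.47	-90.42
CID6136	Thonzylamine Hydrochloride	6136	Anti-Allergic Agents (Histamine H1 Antagonist)	Anti-Allergic Agents	FDA	33.23	1.69	-94.91
CID5702169	Mebhydrolin Naphthalenesulfonate	5702169	Anti-Allergic Agents (Histamine H1 Antagonist)	Anti-Allergic Agents	INN, BAN, MI, JAN	25.34	1.93	-92.39
CID5281070	Dexchlorpheniramine Maleate	5281070	Anti-Allergic Agents (Histamine H1 Antagonist)	Anti-Allergic Agents	FDA	24.82	0.56	-97.76
CID5282408	Ketotifen Fumarate	5282408	Anti-Allergic Agents (Histamine H1 Antagonist)	Anti-Allergic Agents	FDA	23.14	0.81	-96.52
CID3957	Loratadine	3957	Anti-Allergic Agents (Histamine H1 Antagonist)	Anti-Allergic Agents	FDA	21.95	-3.30	-115.04
CID5702129	Triprolidine Hydrochloride	5702129	Anti-Allergic Agents (Histamine H1 Antagonist)	Anti-Allergic Agents	FDA	20.71	0.68	-96.71
CID3827	Ketotifen	3827	Anti-Allergic Agents (Histamine H1 Antagonist)	Anti-Allergic Agents	FDA	20.12	1.38	-93.13
CID124087	Desloratidine	124087	Anti-Allergic Agents (Histamine H1 Antagonist)	Anti-Allergic Agents	FDA	19.79	0.29	-98.52
CID6834	Brompheniramine	6834	Anti-Allergic Agents (Histamine H1 Antagonist)	Anti-Allergic Agents	FDA	18.22	0.64	-96.48
CID10074640	Masitinib	10074640	Antineoplastic Agents	Antineoplastic Agents	INN	27.71	3.82	-86.20
CID11626560	Crizotinib	11626560	Antineoplastic Agents	Antineoplastic Agents	FDA	22.06	-0.44	-101.99
CID50225	Buserelin	50225	Antineoplastic Agents	Antineoplastic Agents	FDA	20.46	5.73	-71.99
CID11442891	Danusertib	11442891	Antineoplastic Agents	Antineoplastic Agents	INN	20.37	0.61	-97.00
CID10206	Cepharanthine	10206	Antineoplastic Agents	Antineoplastic Agents	JAN	19.73	1.14	-94.20
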