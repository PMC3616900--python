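lineage	genome	tfs	target_genes	target_operons	interactions
Streptococcaceae	L. lactis cremoris SK11	36	255	125	130
Streptococcaceae	L. lactis lactis Il1403	34	244	128	138
Streptococcaceae	S. thermophilus CNRZ1066	30	263	125	141
Streptococcaceae	S. agalactiae 2603 V/R	38	340	159	186
Streptococcaceae	S. uberis 0140 J	42	330	156	183
Streptococcaceae	S. equi MGCS10565	42	334	143	167
Streptococcaceae	S. dysgalactiae GGS_124	43	356	160	189
Streptococcaceae	S. pyogenes M1 GAS	40	319	150	180
Streptococcaceae	S. gallolyticus UCN34	41	328	167	199
Streptococcaceae	S. mutans UA159	41	317	147	173
Streptococcaceae	S. suis 05ZYH33	43	366	145	173
Streptococcaceae	S. mitis B6	35	305	148	174
Streptococcaceae	S. pneumoniae TIGR4	42	365	167	206
Streptococcaceae	S. gordonii CH1	41	312	167	194
Streptococcaceae	S. sanguinis SK36	43	339	163	191
Lactobacillaceae	L. sakei 23 K	36	186	92	106
Lactobacillaceae	L. casei ATCC 334	41	226	110	120
Lactobacillaceae	L. rhamnosus GG	42	237	106	116
Lactobacillaceae	L. delbrueckii ATCC BAA-365	18	69	36	37
Lactobacillaceae	L. acidophilus NCFM	27	165	80	90
Lactobacillaceae	L. helveticus DPC 4571	21	91	53	55
Lactobacillaceae	L. johnsonii NCC 533	26	145	78	87
Lactobacillaceae	P. pentosaceus ATCC 25745	38	205	97	111
Lactobacillaceae	L. brevis ATCC 367	39	217	112	128
Lactobacillaceae	L. plantarum WCFS1	46	299	147	170
Lactobacillaceae	L. fermentum IFO 3956	30	172	85	101
Lactobacillaceae	L. reuteri JCM 1112	32	167	83	96
Lactobacillaceae	O. oeni PSU-1	25	109	59	70
Lactobacillaceae	L. mesenteroides ATCC 8293	32	202	89	103
Lactobacillaceae	L. salivarius UCC118	31	198	86	96
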