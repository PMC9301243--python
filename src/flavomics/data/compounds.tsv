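peak	rt_min	name	aglycone	residues
1	4.60	Peonidin Glc I	Peonidin	Glc
2	4.61	Tricin GlcGlcA I	Tricin	Glc,GlcA
3	5.07	Afrormosin Glc I	Afrormosin	Glc
4	5.13	Tricin GlcGlcA II	Tricin	Glc,GlcA
5	5.18	Apigenin GlcAGlcA	Apigenin	GlcA,GlcA
6	5.39	Chrysoeriol GlcAGlcA	Chrysoeriol	GlcA,GlcA
7	5.49	Tricin GlcAGlcA	Tricin	GlcA,GlcA
8	5.77	Tricin GlcGlcA III	Tricin	Glc,GlcA
9	5.81	Apigenin FerGlcAGlcAGlcA I	Apigenin	Fer,GlcA,GlcA,GlcA
10	5.90	Apigenin CouGlcAGlcAGlcA I	Apigenin	Cou,GlcA,GlcA,GlcA
11	5.93	Formononetin Glc I	Formononetin	Glc
12	5.96	Peonidin Glc II	Peonidin	Glc
13	5.97	Chrysoeriol FerGlcAGlcAGlcA	Chrysoeriol	Fer,GlcA,GlcA,GlcA
14	6.03	Tricin Glc I	Tricin	Glc
15	6.08	Apigenin FerGlcAGlcAGlcA II	Apigenin	Fer,GlcA,GlcA,GlcA
16	6.19	Apigenin GlcA	Apigenin	GlcA
17	6.29	Biochanin A MalGlc I	Biochanin A	Mal,Glc
18	6.30	Apigenin CouGlcAGlcAGlcA II	Apigenin	Cou,GlcA,GlcA,GlcA
19	6.32	Apigenin FerGlcAGlcA I	Apigenin	Fer,GlcA,GlcA
20	6.36	Apigenin CouGlcAGlcA I	Apigenin	Cou,GlcA,GlcA
21	6.40	Peonidin Glc III	Peonidin	Glc
22	6.40	Apigenin FerGlcAGlcAGlcA III	Apigenin	Fer,GlcA,GlcA,GlcA
23	6.41	Chrysoeriol GlcA	Chrysoeriol	GlcA
24	6.48	Tricin Glc II	Tricin	Glc
25	6.53	Tricin FerGlcAGlcA I	Tricin	Fer,GlcA,GlcA
26	6.58	Apigenin FerGlcAGlcA II	Apigenin	Fer,GlcA,GlcA
27	6.61	Tricin CouGlcAGlcA I	Tricin	Cou,GlcA,GlcA
28	6.72	Tricin Glc III	Tricin	Glc
29	6.83	Formononetin Glc II	Formononetin	Glc
30	6.92	Apigenin CouGlcAGlcA II	Apigenin	Cou,GlcA,GlcA
31	6.94	Daidzein	Daidzein
32	6.95	Biochanin A MalGlc II	Biochanin A	Mal,Glc
33	6.97	Afrormosin Glc II	Afrormosin	Glc
34	7.06	Tricin CouGlcAGlcA II	Tricin	Cou,GlcA,GlcA
35	7.19	Tricin FerGlcAGlcA III	Tricin	Fer,GlcA,GlcA
36	7.29	Naringenin Chalcone Glc	Naringenin Chalcone	Glc
37	7.60	Medicarpin MalGlc I	Medicarpin	Mal,Glc
38	7.67	Formononetin MalGlc	Formononetin	Mal,Glc
39	7.71	Afrormosin MalGlc	Afrormosin	Mal,Glc
40	8.07	Tricin Glc IV	Tricin	Glc
41	8.15	Medicarpin MalGlc II	Medicarpin	Mal,Glc
42	8.24	Biochanin A	Biochanin A
43	8.39	Irisolidone isomer	Irisolidone
44	8.56	Formononetin	Formononetin
45	8.64	Afrormosin	Afrormosin
46	9.11	Irisolidone	Irisolidone
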