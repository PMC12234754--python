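No	Group	Subgroup	TNM	Histopathology
1	Oral cavity	Tongue	T2 N2c MX	SCC
2	Oropharynx	Tonsil	T4a N1 M0	SCC
3	Oropharynx	Tonsil	T2 N1 MX	SCC
4	Larynx	Glottis	T1 N1 M0	SCC
5	Oropharynx	Tonsil	T4a N2b MX	SCC
6	Larynx	Glottis	T3 N2 M0	SCC
7	Hypopharynx	Sinus piriformis	T3 N0 M0	SCC
8	Oropharynx	Tonsil	T2 N0 M0	SCC
9	Oral cavity	Tongue	T2 N2b M0	SCC
10	Oropharynx	Tonsil	T3c N2c M0	SCC
11	Hypopharynx	Sinus piriformis	T2N N2b M0	SCC
12	Oropharynx	Tonsil	T2 N0 M0	SCC
13	Hypopharynx	Sinus piriformis	T4 N3b M1	SCC
14	Oropharynx	Tonsil	T4 N2 M0	SCC
15	Larynx	Supraglottis	T4 N2 M0	SCC
16	Oropharynx	Tonsil	T2 N1 M0	SCC
17	Larynx	Glottis	T1 N0 M1	SCC
18	Oral cavity	Tongue	T3 N2 MX	SCC
19	Larynx	Glottis	T2 N0 M0	SCC
20	Oral cavity	Tongue	T3 N3b M0	SCC
21	Larynx	Glottis	T1 N0 MX	SCC
22	Oropharynx	Soft palate	T1 N1 M1	SCC
23	Oral cavity	Tongue	T1 NX M0	SCC
24	Larynx	Glottis	T1 N0 MX	SCC
25	Oral cavity	Tongue	T3 N2 MX	SCC
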