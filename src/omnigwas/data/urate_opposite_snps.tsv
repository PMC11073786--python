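variant	chr	pos	info	major	minor	maf_all	maf_F	maf_M	beta_F	beta_M	p_F	p_M	p_diff	p_metaL	p_metaQ
rs6814556	4	10004389	0.999	A	G	0.268	0.268	0.268	-3.184	2.285	4.91E-40	1.44E-15	1.77E-48	5.37E-07	1.14E-52
rs6833878	4	10005555	1.000	A	T	0.268	0.268	0.268	-3.169	2.277	1.09E-39	1.80E-15	4.25E-48	6.25E-07	3.14E-52
rs3796834	4	10012846	1.000	C	T	0.279	0.279	0.279	-3.704	2.056	8.14E-55	3.47E-13	6.77E-55	3.86E-13	4.73E-65
rs3796833	4	10012878	1.000	C	T	0.279	0.279	0.279	-3.714	2.052	4.33E-55	3.86E-13	5.31E-55	2.88E-13	2.81E-65
rs1122966	4	10014476	1.000	G	A	0.280	0.279	0.280	-3.813	2.002	4.36E-58	1.32E-12	4.90E-56	1.00E-14	9.63E-68
rs6857001	4	10018080	1.000	G	A	0.280	0.280	0.280	-3.837	1.980	7.88E-59	2.24E-12	4.06E-56	3.63E-15	2.93E-68
rs3796830	4	10019135	1.000	G	C	0.279	0.279	0.279	-3.742	2.033	6.43E-56	6.18E-13	3.38E-55	1.05E-13	6.58E-66
rs28449404	4	10019678	1.000	C	G	0.279	0.279	0.279	-3.738	2.033	8.34E-56	6.21E-13	4.03E-55	1.15E-13	8.64E-66
rs10030570	4	10027160	1.000	G	T	0.280	0.280	0.280	-3.687	2.100	1.79E-54	9.98E-14	1.51E-55	1.12E-12	3.03E-65
rs6819833	4	10027354	1.000	C	G	0.280	0.280	0.280	-3.687	2.100	1.85E-54	1.01E-13	1.55E-55	1.13E-12	3.14E-65
rs6820230	4	10027542	1.000	C	T	0.280	0.280	0.280	-3.691	2.095	1.41E-54	1.15E-13	1.62E-55	9.45E-13	2.76E-65
rs6449237	4	10027643	1.000	A	G	0.280	0.280	0.281	-3.689	2.095	1.60E-54	1.15E-13	1.77E-55	9.86E-13	3.13E-65
rs6449238	4	10027744	1.000	G	A	0.280	0.280	0.280	-3.689	2.100	1.60E-54	1.01E-13	1.43E-55	1.07E-12	2.75E-65
rs7697004	4	10028077	1.000	G	A	0.280	0.280	0.281	-3.686	2.101	1.95E-54	9.77E-14	1.54E-55	1.18E-12	3.25E-65
rs7697416	4	10028287	0.999	G	A	0.281	0.280	0.281	-3.659	2.105	1.13E-53	8.62E-14	3.95E-55	2.38E-12	1.66E-64
rs7669699	4	10028438	1.000	C	T	0.280	0.280	0.280	-3.693	2.097	1.24E-54	1.10E-13	1.38E-55	9.32E-13	2.32E-65
rs9291645	4	10038254	0.997	G	A	0.281	0.281	0.282	-3.654	2.145	1.43E-53	2.97E-14	9.00E-56	4.65E-12	7.31E-65
rs6850166	4	10043688	0.997	C	T	0.281	0.281	0.281	-3.709	2.115	4.09E-55	6.94E-14	3.38E-56	7.99E-13	4.89E-66
rs4391034	4	10049700	0.996	T	C	0.282	0.281	0.282	-3.688	2.105	1.59E-54	9.03E-14	1.25E-55	1.10E-12	2.46E-65
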