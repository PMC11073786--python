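variant	chr	pos	info	major	minor	maf_all	maf_F	maf_M	beta_F	beta_M	p_F	p_M	p_diff	p_metaL	p_metaQ
rs4308991	1	93418330	0.987	T	A	0.398	0.398	0.397	-0.007	0.068	2.01E-03	5.73E-07	5.20E-08	2.69E-02	3.16E-08
rs2638052	1	101956313	0.999	A	T	0.340	0.341	0.339	-0.01	0.059	9.95E-06	2.45E-05	9.76E-07	2.58E-04	7.84E-09
rs72697614	1	107514107	0.972	A	C	0.321	0.320	0.322	0.008	0.078	8.90E-04	5.06E-08	1.44E-06	2.85E-05	1.42E-09
rs1672939	3	138276133	0.999	T	C	0.449	0.449	0.449	0.006	0.072	5.37E-03	6.31E-08	1.11E-06	2.67E-04	9.15E-09
rs150750289	4	3443769	0.950	T	C	0.024	0.024	0.024	-0.025	-0.209	7.52E-04	1.83E-06	3.45E-05	3.78E-05	3.88E-08
rs4946386	6	119322992	0.984	T	C	0.302	0.302	0.302	0.013	-0.037	1.91E-07	1.08E-02	7.28E-04	2.44E-06	4.99E-08
rs117916257	10	65387009	0.976	G	A	0.044	0.044	0.044	-0.015	-0.176	7.17E-03	5.69E-08	9.26E-07	3.81E-04	1.07E-08
rs7943570	11	48085968	0.994	T	C	0.090	0.090	0.090	-0.009	-0.125	2.40E-02	6.86E-08	7.68E-07	1.78E-03	3.74E-08
rs2241235	17	7381366	0.982	C	T	0.141	0.140	0.142	-0.009	-0.099	8.08E-03	1.87E-07	2.65E-06	4.96E-04	3.77E-08
rs8087735	18	71977923	0.979	G	A	0.140	0.140	0.139	0.017	-0.045	7.45E-08	1.96E-02	1.39E-03	8.80E-07	3.39E-08
rs117599084	19	49530502	0.890	A	T	0.073	0.074	0.073	0.018	0.114	8.15E-05	1.91E-05	3.72E-04	4.29E-06	4.58E-08
rs146539762	23	65720145	0.943	A	G	0.017	0.017	0.017	-0.021	-0.196	1.91E-02	9.98E-08	3.57E-06	4.33E-04	4.42E-08
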