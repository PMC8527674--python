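cpg	chr	pos	gene	trait	stratum	beta_mean	beta_sd	effect	se	p
cg02871985	2	43398154	THADA	BMI	MEC_Chinese	0.11	0.02	-21.61	22.03	3.29e-01
cg02871985	2	43398154	THADA	BMI	iOmics_Chinese	0.18	0.02	-57.56	21.15	7.91e-03
cg02871985	2	43398154	THADA	BMI	iOmics_Indian	0.18	0.03	-56.94	16.23	7.45e-04
cg02871985	2	43398154	THADA	BMI	iOmics_Malay	0.18	0.02	-46.00	31.00	1.43e-01
cg07421368	2	67624930	ETAA1	BMI	MEC_Chinese	0.02	0.01	41.17	60.71	4.99e-01
cg07421368	2	67624930	ETAA1	BMI	iOmics_Chinese	0.05	0.04	43.10	8.66	3.43e-06
cg07421368	2	67624930	ETAA1	BMI	iOmics_Indian	0.05	0.01	-27.33	58.40	6.41e-01
cg07421368	2	67624930	ETAA1	BMI	iOmics_Malay	0.05	0.01	-114.23	76.50	1.40e-01
cg07421368	2	67624930	ETAA1	WC	MEC_Chinese	0.02	0.01	-32.44	157.58	8.37e-01
cg07421368	2	67624930	ETAA1	WC	iOmics_Chinese	0.05	0.04	114.79	21.47	7.56e-07
cg07421368	2	67624930	ETAA1	WC	iOmics_Indian	0.05	0.01	-29.78	134.76	8.26e-01
cg07421368	2	67624930	ETAA1	WC	iOmics_Malay	0.05	0.01	-148.44	176.17	4.03e-01
cg15103625	3	157826388	RSRC1	BMI	MEC_Chinese	0.16	0.03	27.79	13.01	3.48e-02
cg15103625	3	157826388	RSRC1	BMI	iOmics_Chinese	0.28	0.04	40.45	10.43	2.09e-04
cg15103625	3	157826388	RSRC1	BMI	iOmics_Indian	0.27	0.03	36.50	17.87	4.45e-02
cg15103625	3	157826388	RSRC1	BMI	iOmics_Malay	0.28	0.04	19.14	16.35	2.46e-01
cg15103625	3	157826388	RSRC1	WC	MEC_Chinese	0.16	0.03	75.44	33.63	2.69e-02
cg15103625	3	157826388	RSRC1	WC	iOmics_Chinese	0.28	0.04	102.90	26.25	1.80e-04
cg15103625	3	157826388	RSRC1	WC	iOmics_Indian	0.27	0.03	105.78	40.56	1.09e-02
cg15103625	3	157826388	RSRC1	WC	iOmics_Malay	0.28	0.04	60.89	36.86	1.03e-01
cg08010984	3	170964901	TNIK	BMI	MEC_Chinese	0.43	0.05	-27.83	7.95	6.64e-04
cg08010984	3	170964901	TNIK	BMI	iOmics_Chinese	0.54	0.05	-26.15	10.84	1.81e-02
cg08010984	3	170964901	TNIK	BMI	iOmics_Indian	0.53	0.05	-18.96	13.22	1.55e-01
cg08010984	3	170964901	TNIK	BMI	iOmics_Malay	0.55	0.04	-19.62	16.18	2.30e-01
cg16309866	7	41264719	LINC01449	BMI	MEC_Chinese	0.53	0.05	-33.93	9.94	8.94e-04
cg16309866	7	41264719	LINC01449	BMI	iOmics_Chinese	0.60	0.05	-47.72	13.29	5.57e-04
cg16309866	7	41264719	LINC01449	BMI	iOmics_Indian	0.61	0.05	-4.81	16.94	7.77e-01
cg16309866	7	41264719	LINC01449	BMI	iOmics_Malay	0.60	0.05	-18.86	27.56	4.96e-01
cg19120513	11	102189303	BIRC3	BMI	MEC_Chinese	0.38	0.05	-28.23	11.33	1.42e-02
cg19120513	11	102189303	BIRC3	BMI	iOmics_Chinese	0.47	0.05	-35.98	14.83	1.74e-02
cg19120513	11	102189303	BIRC3	BMI	iOmics_Indian	0.45	0.06	-34.31	15.82	3.31e-02
cg19120513	11	102189303	BIRC3	BMI	iOmics_Malay	0.46	0.06	-51.67	18.94	8.17e-03
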