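snp_id	coefficient	SAS	AFR	EUR	AMR	EAS
rs12979986	-1	0.26	0.08	0.34	0.34	0.21
rs9625031	-1	0.14	0.02	0.29	0.19	0.23
rs1931229	-1	0.35	0.10	0.28	0.33	0.50
rs1660281	1	0.26	0.49	0.11	0.21	0.38
rs10064620	1	0.41	0.26	0.37	0.32	0.26
rs10860210	-1	0.45	0.50	0.38	0.46	0.32
rs941207	1	0.16	0.08	0.26	0.25	0.26
rs9868579	-1	NA	NA	NA	NA	NA
rs62174680	1	0.29	0.03	0.32	0.28	0.34
rs11232056	1	0.26	0.28	0.17	0.41	0.47
rs8124833	1	0.10	0.20	0.13	0.25	0.39
rs74522810	-1	0.20	0.18	0.21	0.18	0.18
rs74369678	-1	NA	NA	NA	NA	NA
chr3:74213366	1	NA	NA	NA	NA	NA
rs2035081	-1	0.22	0.33	0.38	0.33	0.26
rs79404120	1	0.17	0.01	0.14	0.11	0.16
rs11672661	-1	0.40	0.06	0.48	0.48	0.43
rs28625772	1	0.05	0.30	0.06	0.07	0.08
rs9298681	1	0.24	0.47	0.20	0.45	0.26
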