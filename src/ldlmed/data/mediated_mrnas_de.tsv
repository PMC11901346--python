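gene	logfc_ldl	p_ldl	fdr_ldl	logfc_sdldl	p_sdldl	fdr_sdldl
RNF182	-0.49	8.74e-18	2.61e-14	-0.34	3.88e-08	1.55e-05
TNS1	0.42	4.42e-17	8.81e-14	0.31	3.56e-09	2.00e-06
SLC12A1	-0.59	8.76e-17	1.57e-13	-0.28	1.10e-04	1.11e-02
ITGB3	0.40	3.43e-15	4.74e-12	0.20	1.02e-04	1.05e-02
RBM38	0.38	3.06e-14	3.43e-11	0.39	2.86e-13	3.95e-10
PF4	0.40	1.19e-13	1.02e-10	0.26	2.57e-06	5.01e-04
DMTN	0.38	1.46e-13	1.19e-10	0.23	1.96e-05	2.79e-03
NPRL3	0.40	2.08e-13	1.62e-10	0.29	3.22e-07	8.22e-05
MYOM2	0.43	4.24e-13	3.17e-10	0.31	2.23e-06	4.49e-04
FKBP8	0.33	3.68e-11	1.83e-08	0.25	1.64e-06	3.47e-04
RUNDC3A	0.34	1.78e-09	5.07e-07	0.40	5.33e-11	4.35e-08
RAD23A	0.36	2.29e-09	6.41e-07	0.25	8.51e-05	9.31e-03
TRIM58	0.30	2.40e-09	6.62e-07	0.28	1.85e-07	5.54e-05
BCL2L1	0.28	9.35e-09	2.12e-06	0.20	1.00e-04	1.04e-02
GUK1	0.29	1.01e-08	2.26e-06	0.19	4.78e-04	3.40e-02
E2F2	0.29	2.94e-08	5.80e-06	0.21	1.13e-04	1.13e-02
EVI2A	-0.29	5.00e-08	9.07e-06	-0.19	6.05e-04	4.08e-02
ASCC2	0.26	1.09e-07	1.76e-05	0.23	1.81e-05	2.63e-03
MRC2	0.31	1.27e-07	1.99e-05	0.24	1.73e-04	1.59e-02
MARCHF8	0.26	1.34e-07	2.07e-05	0.23	1.13e-05	1.78e-03
CARM1	0.31	1.74e-07	2.51e-05	0.21	6.90e-04	4.54e-02
CXCL5	0.31	2.49e-07	3.29e-05	0.25	8.74e-05	9.43e-03
TUBB2A	0.26	5.53e-07	6.65e-05	0.34	2.29e-09	1.37e-06
TMCC2	0.28	3.04e-06	2.58e-04	0.30	2.36e-06	4.66e-04
DCAF12	0.23	3.83e-06	3.07e-04	0.19	2.67e-04	2.24e-02
KLF1	0.26	5.75e-06	4.30e-04	0.24	7.39e-05	8.44e-03
HBQ1	0.52	9.17e-06	6.25e-04	0.56	4.49e-06	8.14e-04
ATOSB	0.23	1.91e-05	1.11e-03	0.23	8.78e-05	9.43e-03
DNAJA4	0.23	2.21e-05	1.24e-03	0.24	6.62e-05	7.76e-03
GYPB	0.21	2.25e-04	7.56e-03	0.24	4.64e-05	5.78e-03
BLVRB	0.18	2.52e-04	8.18e-03	0.23	2.10e-05	2.97e-03
ROGDI	0.21	1.29e-03	2.77e-02	0.25	3.97e-04	3.02e-02
IL4R	0.16	1.46e-03	3.01e-02	0.20	1.81e-04	1.65e-02
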