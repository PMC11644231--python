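gene	mean_ctrl	mean_trt	fold_change	qvalue
ABRAXAS1	257.87	311.56	0.27	2.91e-2
BRCA1	7573.63	8576.82	0.18	1.50e-5
BRCA2	6125.88	6979.65	0.19	1.76e-3
CDKN1A	721.77	1039.85	0.53	2.32e-3
FANCA	10898.09	11329.24	0.06	1.95e-3
FANCD2	13431.01	14889.88	0.15	2.31e-2
FANCE	1892.62	2051.59	0.12	9.40e-3
KDM1A	10353.58	9712.88	-0.09	3.92e-2
NBN	1756.94	1911.43	0.12	9.29e-3
XPC	5391.15	5912.85	0.13	1.50e-9
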