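# Published tumor/normal paired proteomic dominance counts for interferon-pathway candidate genes (97 pairs).
gene_id	n_high_normal	frac_normal_printed	n_high_cancer	frac_cancer_printed
GZMA	77	79.38	20	20.62
HLA-DPA1	76	78.35	21	21.65
APOL1	74	76.29	23	23.71
DDX60	73	75.26	24	24.74
ISG15	68	70.10	29	29.90
BTN3A3	64	65.98	33	34.02
CMPK2	64	65.98	33	34.02
HLA-DMB	61	62.89	35	37.11
ISG20	61	62.89	36	37.11
DDX58	57	58.76	40	41.24
APOL3	55	56.70	42	43.30
HLA-DRA	55	56.70	42	43.30
HLA-DRB1	54	55.67	43	44.33
HLA-F	51	52.58	46	47.42
IFI35	49	50.52	48	49.48
TRIM22	49	50.52	48	49.48
PARP12	48	49.48	49	50.52
IFIT3	46	47.42	51	52.58
OASL	42	43.30	55	56.70
APOL2	37	38.14	60	61.86
CD74	36	37.11	61	62.89
GBP4	34	35.05	63	64.95
HLA-E	34	35.05	63	64.95
GBP2	34	35.05	63	64.95
GBP1	33	34.02	64	65.98
SERPINB9	33	34.02	64	65.98
PARP14	30	30.93	67	69.07
PARP9	27	27.84	70	72.16
UBE2L6	27	27.84	70	72.16
PSMB9	25	25.77	72	74.23
TYMP	21	21.65	76	78.35
STAT1	15	15.46	82	84.54
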