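model_name	purity_pct	n_somatic	cancer
Pan02	78	204	Pancreatic cancer
MBT2	78.7	1194	Bladder cancer
EMT6	80.6	214	Breast cancer
LL2	81.7	1741	Lung cancer
WEHI164	83.4	848	Fibrosarcoma
4T1	83.6	66	Breast cancer
Renca	84.8	654	Kidney cancer
RM1	87.2	60	Prostate cancer
MC38	88	1662	Colorectal cancer
CT26	88.2	1027	Colorectal cancer
EL4	89.5	879	Lymphoma
EG7OVA	90.6	563	Lymphoma
A20	92.1	320	Lymphoma
B16F10	94.3	458	Melanoma
Colon26	94.3	783	Colorectal cancer
H22	95.3	3447	Liver cancer
J558	96	75	Plasmacytoma
B16BL6	96.3	559	Melanoma
KLN205	96.3	532	Lung cancer
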