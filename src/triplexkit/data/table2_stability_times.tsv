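gene_id	mirna1_id	mirna2_id	d1_ps	d2_ps	t1_ps	t2_ps	group_label
RPS6KA5	miR-410	miR-590-3p	139	145	62	92	high_mfe
HTRA2	miR-374a	miR-374a	72	72	116	75	high_mfe
ZNF121	miR-374a	miR-374a	250	250	58	91	high_mfe
EDA2R	miR-125a-3p	miR-370	206	468	218	449	low_mfe
MUC1	miR-145	miR-326	249	192	179	500	low_mfe
ABT1	miR-214	miR-491-5p	327	338	239	399	low_mfe
GOLM1	miR-296-3p	miR-330-5p	500	395	118	500	high_gain
CCDC3	miR-138	miR-551b	500	479	500	500	high_gain
PLXNB1	miR-197	miR-320d	333	74	207	387	high_gain
NPHP1	miR-194	miR-340	113	203	47	44	low_gain
KAT2B	miR-106b	miR-590-3p	106	323	500	100	low_gain
C19orf69	miR-190	miR-590-3p	257	214	74	196	low_gain
CDKN1A	miR-572	miR-93	42	301	126	473	control
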