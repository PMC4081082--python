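gene_id	mirna1_id	mirna2_id	dG_triplex	ddG	group_label
RPS6KA5	miR-410	miR-590-3p	-12.263	-4.782	high_mfe
HTRA2	miR-374a	miR-374a	-11.363	-3.982	high_mfe
ZNF121	miR-374a	miR-374a	-10.363	-4.682	high_mfe
EDA2R	miR-125a-3p	miR-370	-57.963	-22.282	low_mfe
MUC1	miR-145	miR-326	-55.963	-15.282	low_mfe
ABT1	miR-214	miR-491-5p	-51.163	-16.182	low_mfe
GOLM1	miR-296-3p	miR-330-5p	-47.263	-21.482	high_gain
CCDC3	miR-138	miR-551b	-55.263	-21.782	high_gain
PLXNB1	miR-197	miR-320d	-49.863	-23.482	high_gain
NPHP1	miR-194	miR-340	-16.963	-1.782	low_gain
KAT2B	miR-106b	miR-590-3p	-22.263	-1.682	low_gain
C19orf69	miR-190	miR-590-3p	-25.063	-1.582	low_gain
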