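# Loop penalty parameters of the reduced nearest-neighbor model.
# Energies in kcal/mol at 310.15 K; sizes in nucleotides.
# hairpin(n)        = hairpin_base + hairpin_log * ln(n / 3), n >= 3
# bulge(n)          = bulge_base + bulge_log * ln(n)
# internal(n1, n2)  = internal_base + internal_log * ln((n1 + n2) / 2)
#                     + min(asym_max, internal_asym * |n1 - n2|)
# multiloop         = ml_base + ml_branch * (branches incl. closing) + ml_unpaired * n
# Internal/bulge loops with n1 + n2 > max_loop are disallowed; loops
# containing a strand nick carry no penalty (exterior-like).
param	value
hairpin_base	5.40
hairpin_log	1.08
bulge_base	3.80
bulge_log	1.08
internal_base	4.00
internal_log	1.08
internal_asym	0.50
asym_max	3.00
ml_base	3.40
ml_branch	0.40
ml_unpaired	0.10
max_loop	30
hairpin_min	3
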