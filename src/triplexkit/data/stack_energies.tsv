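# Helix stacking free energies, kcal/mol at 310.15 K.
# pair1 = (5' base, 3' base) of the outer base pair (i, j); pair2 = the inner
# base pair (i+1, j-1).  Entries are symmetrized on load:
# stack(xy, wz) = stack(zw, yx); listing one member of each symmetric pair
# suffices.  Watson-Crick values follow the standard nearest-neighbor set;
# G.U wobble values are the reduced-model set documented in docs/methods.md.
pair1	pair2	dG
AU	AU	-0.93
AU	UA	-1.10
UA	AU	-1.33
CG	UA	-2.08
CG	AU	-2.11
GC	UA	-2.24
GC	AU	-2.35
CG	GC	-2.36
GC	GC	-3.26
GC	CG	-3.42
AU	GU	-0.80
AU	UG	-1.00
UA	GU	-0.80
UA	UG	-1.00
CG	GU	-1.50
CG	UG	-1.90
GC	GU	-1.30
GC	UG	-2.10
GU	GU	-0.50
GU	UG	0.30
UG	GU	-0.60
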