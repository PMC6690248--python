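outer	inner	dg_kcal_mol
AU	AU	-0.90
AU	CG	-2.20
AU	GC	-2.10
AU	GU	-0.60
AU	UA	-1.10
AU	UG	-1.40
CG	AU	-2.10
CG	CG	-3.30
CG	GC	-2.40
CG	GU	-1.40
CG	UA	-2.10
CG	UG	-2.10
GC	AU	-2.40
GC	CG	-3.40
GC	GC	-3.30
GC	GU	-1.50
GC	UA	-2.20
GC	UG	-2.50
GU	AU	-1.30
GU	CG	-2.50
GU	GC	-2.10
GU	GU	-0.50
GU	UA	-1.40
GU	UG	1.30
UA	AU	-1.30
UA	CG	-2.40
UA	GC	-2.10
UA	GU	-1.00
UA	UA	-0.90
UA	UG	-1.30
UG	AU	-1.00
UG	CG	-1.50
UG	GC	-1.40
UG	GU	0.30
UG	UA	-0.60
UG	UG	-0.50
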