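# Nearest-neighbor RNA:RNA stack free energies, kcal/mol, 37 C.
# Watson-Crick stacks: Xia et al. 1998 values; G:U wobble stacks are
# simplified uniformly-negative placeholders (internally consistent,
# symmetric under strand exchange). Format:
#   stack <pair1> <pair2> <dG>  pair = strand1 base + strand2 base;
#   pair2 is the adjacent pair 3' on strand 1 / 5' on strand 2.
#   param <name> <value>        loop penalties and duplex initiation.
stack	AU	AU	-0.93
stack	AU	CG	-2.24
stack	AU	GC	-2.08
stack	AU	GU	-0.70
stack	AU	UA	-1.10
stack	AU	UG	-0.70
stack	CG	AU	-2.11
stack	CG	CG	-3.26
stack	CG	GC	-2.36
stack	CG	GU	-1.50
stack	CG	UA	-2.08
stack	CG	UG	-1.50
stack	GC	AU	-2.35
stack	GC	CG	-3.42
stack	GC	GC	-3.26
stack	GC	GU	-1.50
stack	GC	UA	-2.24
stack	GC	UG	-1.50
stack	GU	AU	-0.70
stack	GU	CG	-1.50
stack	GU	GC	-1.50
stack	GU	GU	-0.50
stack	GU	UA	-0.70
stack	GU	UG	-0.50
stack	UA	AU	-1.33
stack	UA	CG	-2.35
stack	UA	GC	-2.11
stack	UA	GU	-0.70
stack	UA	UA	-0.93
stack	UA	UG	-0.70
stack	UG	AU	-0.70
stack	UG	CG	-1.50
stack	UG	GC	-1.50
stack	UG	GU	-0.50
stack	UG	UA	-0.70
stack	UG	UG	-0.50
param	duplex_init	4.09
param	bulge_open	3.80
param	bulge_extend	0.40
param	internal_open	4.10
param	internal_extend	0.40
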