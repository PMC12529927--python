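# Nearest-neighbor free-energy parameters for RNA Watson-Crick duplexes,
# Turner-style deltaG(37C) stacks in kcal/mol.  Stacks are keyed by the
# 5'->3' dinucleotide of one strand; the value for a dinucleotide equals
# that of its reverse-complement (duplex-reversal symmetry).
param	key	dg_kcal_mol
stack	AA	-0.93
stack	UU	-0.93
stack	AU	-1.10
stack	UA	-1.33
stack	CU	-2.08
stack	AG	-2.08
stack	CA	-2.11
stack	UG	-2.11
stack	GU	-2.24
stack	AC	-2.24
stack	GA	-2.35
stack	UC	-2.35
stack	CG	-2.36
stack	GG	-3.26
stack	CC	-3.26
stack	GC	-3.42
init	-	4.09
terminal_au	-	0.45
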