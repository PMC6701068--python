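# Bjellqvist-style ionizable-group pKa constants (as used by the ExPASy
# ProtParam service), including residue-specific N-terminal pKas.
name	bjellqvist
c_term	3.55
n_term_default	7.50
side_chain.D	4.05
side_chain.E	4.45
side_chain.C	9.00
side_chain.Y	10.00
side_chain.H	5.98
side_chain.K	10.00
side_chain.R	12.00
n_term.A	7.59
n_term.M	7.00
n_term.S	6.93
n_term.P	8.36
n_term.T	6.82
n_term.V	7.44
n_term.E	7.70
n_term.G	7.50
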