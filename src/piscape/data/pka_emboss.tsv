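# EMBOSS iep pKa constants (no residue-specific N-terminal values);
# shipped as an alternative scheme for sensitivity checks.
name	emboss
c_term	3.60
n_term_default	8.60
side_chain.D	3.90
side_chain.E	4.10
side_chain.C	8.50
side_chain.Y	10.10
side_chain.H	6.50
side_chain.K	10.80
side_chain.R	12.50
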