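# Intra-organelle pH from two literature surveys and membrane charge
# (summed relative content, %, of the charged phospholipids PS + PI).
# "-" denotes a missing value; pH intervals are written "a-b".
compartment	ph_2009	ph_2015	charge_pct
cytoplasm	7.3	7.2	0.0
nucleus	7.7	7.2	17.4
er	7.1	7.2	17.4
mitochondria	7.5	8.0	10.0
golgi	6.6	6.0-6.7	10.0
peroxisome	8.2	7.0	2.0
lysosome	4.8	4.7	4.7
membrane	-	-	8.5
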