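# pi-scape

Localization-specific protein isoelectric-point (pI) landscapes: from raw
amino-acid sequences to compartment-resolved pI distributions, and to the
question of *why* those distributions differ — how the mean pI of each
subcellular compartment's sub-proteome relates to the organelle's local pH
and the charge of its membrane.

## Who this is for

Computational biologists and proteomics researchers who have (a) a FASTA
file of protein sequences and (b) a table assigning each protein to a
subcellular compartment (e.g. WoLF PSORT predictions, or experimentally
curated sets), and who want reproducible, tested machinery for:

- computing pI from sequence with auditable pKa constants,
- profiling pI distributions per compartment (whole-proteome histograms,
  compartment means, localization composition at reference pI values,
  compartment share along the pI axis),
- correlating localization with pI, and
- searching function families that fit compartment mean pI as a function of
  organelle pH and membrane charge.

## The model

A protein's net charge at pH is a sum of independent Henderson–Hasselbalch
terms over its ionizable groups. Basic groups (N-terminus, His, Lys, Arg)
contribute

    +1 / (1 + 10^(pH − pKa))

and acidic groups (C-terminus, Asp, Glu, Cys, Tyr) contribute

    −1 / (1 + 10^(pKa − pH)).

Each term is strictly decreasing in pH, so the total charge crosses zero
exactly once on [0, 14]; that zero is the isoelectric point, located by
bisection to 0.001 pH and reported to three decimals. The default pKa set is
Bjellqvist-style (as used by the ExPASy ProtParam service), including
residue-specific N-terminal pKas; an EMBOSS-style set ships for sensitivity
checks. Both live in human-readable data files under
`src/piscape/data/`.

Downstream, compartment mean pIs are joined with a built-in organelle
environment table — per-compartment pH averaged from two literature surveys
plus membrane charge, defined as the summed relative content (%) of the
charged phospholipids phosphatidylserine (PS) and phosphatidylinositol (PI)
— and an exhaustive least-squares search ranks candidate function families
(univariate: linear, polynomial, power, exponential, logarithmic; bivariate:
all 511 intercept-plus-monomial-subset polynomials up to total degree 3) by
R² in the original response space, each validated by the Spearman
correlation of fitted vs observed values.

A seeded synthetic-proteome generator closes the loop for testing: it draws
per-compartment target pIs from bimodal (acidic/alkaline peak) mixtures and
materialises each target as an actual sequence whose computed pI matches it,
so every pipeline stage can be exercised end-to-end with known ground truth.

## Worked example

Compute pIs directly:

```
$ pi-scape calc-pi demo.fasta
id	length	pi
sp_P61626	130	9.278
demo_acidic	49	2.848
```

(Lysozyme C, heavily basic, computes to pI 9.278; a synthetic Asp/Glu-rich
peptide to 2.848.)

Simulate a proteome with known compartment structure and profile it:

```
$ pi-scape simulate --out sim --seed 1 --n-per-compartment 300
$ pi-scape profile --fasta sim/proteome.fasta --loc sim/localization.tsv
label	n	mean_pi
all	3000	6.978
cytoplasm	300	6.603
cytoskeleton	300	6.401
er	300	6.687
extracellular	300	6.780
golgi	300	7.294
lysosome	300	6.476
membrane	300	7.557
mitochondria	300	7.766
nucleus	300	7.599
peroxisome	300	6.613
```

The acid-biased compartments (cytoskeleton 6.40, lysosome 6.48, cytoplasm
6.60) and the alkaline-biased ones (mitochondria 7.77, nucleus 7.60,
membrane 7.56) separate exactly as the generator's mixture weights dictate —
the same qualitative split seen in real compartment sub-proteomes.

The full pipeline (`pi-scape run-all --fasta F --loc L --out DIR`) writes
per-protein pIs, per-compartment histograms and means, reference-point
localization profiles, share-vs-pI correlations, the ranked regression fits
against the organelle environment table, and a manifest that replays the run
byte-identically.

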