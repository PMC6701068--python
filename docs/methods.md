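# Methods

## Charge model and pI calculation

The net charge of a protein at a given pH is modelled as a sum of
independent Henderson–Hasselbalch terms: one per ionizable side chain
(Asp, Glu, Cys, Tyr acidic; His, Lys, Arg basic) plus the two termini.
Interactions between sites, local environment shifts, disulfide bonding and
post-translational modifications are all ignored — the calculation is from
raw sequence composition only, which is the standard desk approximation and
agrees well with experimental pI for most soluble proteins. Consequences:

- pI depends only on amino-acid composition plus the identity of the first
  residue (which selects the N-terminal pKa); residue order is irrelevant.
- The charge curve is strictly decreasing in pH, so the pI is the unique
  zero, bracketed on [0, 14] and found by bisection. The bracket is halved
  until narrower than `tol` (default 0.001 pH, ~15 iterations); results are
  reported to three decimals. The bisection midpoint is within 0.0005 of
  the true zero and rounding adds at most 0.0005, so reported values are
  within 0.001 of the model's exact pI.
- Ambiguity letters B, Z, X and selenocysteine U are accepted and carry no
  ionizable group. For sequences rich in them the computed pI is
  correspondingly approximate.

Two pKa schemes ship as data files. `bjellqvist` (default) matches the
constants used by the ExPASy ProtParam service: side chains D 4.05, E 4.45,
C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0; C-terminus 3.55; N-terminus 7.5 with
residue-specific overrides (A 7.59, M 7.00, S 6.93, P 8.36, T 6.82, V 7.44,
E 7.70). `emboss` carries the EMBOSS `iep` constants and no N-terminal
overrides. The exact constants behind the ProtParam web service are not
published alongside every analysis that uses it, so numerical equality with
that service is a calibration statement, not a guarantee; pinning both sets
in versioned data files makes the choice auditable, and the test suite
cross-checks against Biopython's IsoelectricPoint on sequences where the
constant sets coincide.

## Dataset construction filters

Two pre-processing filters mirror common proteome dataset construction:
a minimum length of 50 residues (shorter entries are usually fragments),
and a redundancy screen removing sequences more than 90% identical to a
longer retained sequence. The screen is a greedy k-mer containment
clustering, not a reimplementation of CD-HIT: records are visited in
decreasing-length order (ties by input order), identity between two
sequences is the fraction of the shorter sequence's distinct 5-mers shared
with the other, exact duplicates always drop, and an inverted 5-mer index
keeps the pass near-linear. This is deliberately a documented stand-in —
redundancy removal here is only a preprocessing filter, and its exact
clustering behaviour is not part of any downstream claim. A
`skip_redundancy` flag bypasses it for pre-deduplicated input. The screen is
idempotent and order-preserving.

Localization labels are consumed as annotations (a TSV of id → label), not
predicted. Labels are normalised through a synonym map covering
WoLF-PSORT-style abbreviations (`cyto`, `nucl`, `plas`, `mito`, `cysk`,
`E.R.`, …) onto a controlled vocabulary of ten compartments plus `multi`
for proteins annotated to multiple compartments. How a multi-compartment
call is derived from a predictor's score list is the annotator's decision;
this package takes the label as given.

## Organelle environment covariates

The built-in environment table carries, per compartment: pH observations
from two literature compilations (2009 and 2015), their average, and the
membrane charge, defined as the summed relative content (%) of the charged
phospholipids PS and PI in that organelle's membrane. Choices made where
the sources leave room:

- A pH reported as an interval (Golgi: 6.0–6.7) collapses to its midpoint
  before averaging — the minimal-assumption reading of "averaged values".
  Golgi therefore averages to 6.475, lysosome to 4.75, cytoplasm to 7.25.
- The plasma membrane has a membrane charge but no intra-organelle pH (it
  is a boundary, not a lumen); it is excluded, with a logged notice, from
  any computation requiring pH. Seven compartments carry both covariates.
- Cytoskeleton has no environment row and is additionally excluded from the
  compartment regression by default: cytoskeletal proteins polymerize and
  are not truly soluble, making their strongly acid-biased mean pI an
  outlier with a different mechanism.

## Distribution profiling

Histograms use half-open bins of width 0.25 pH over [3.0, 13.0] (the
quarter-unit grid on which the canonical acidic/alkaline peak positions 6.0
and 8.25 sit); values outside the range are clipped into the terminal bins,
and subset means are computed on raw values, never on bin midpoints.
Reference points along the pI axis default to (4.75, 6.0, 7.0, 8.25, 9.5,
11.5): the acidic shoulder at 4.75 and the extra-alkaline sub-peak above
11.5 are fixed landmarks of whole-proteome distributions; the middle four
(major peaks, neutral trough, alkaline flank) are configurable placements,
since such features are usually identified by eye on the histogram.

The share of a compartment along the pI axis is computed per bin (fraction
of the bin's proteins carrying the label), with bins holding fewer than 20
proteins omitted — near-empty tail bins otherwise produce spurious extreme
shares. A cumulative mode (running share among all proteins up to the bin's
upper edge) is also provided; "cumulative linearized" share plots can be
read either way, so both are implemented, with the per-bin mode the default
for correlation because consecutive cumulative values are strongly
autocorrelated and would overstate significance.

## Correlation kernel

Pearson's r with the exact two-tailed p from t = r·√((n−2)/(1−r²)) on n−2
degrees of freedom; Spearman's rs as the Pearson correlation of mean ranks
(ties receive average ranks) with the same t transform — matching the
behaviour of the common online statistics calculators — plus an exact
permutation p (all n! rank permutations) available for n ≤ 10, where the t
approximation is least trustworthy. For the reference pair rs = 0.69 at
n = 8 the t approximation gives p = 0.058. R² is 1 − SS_res/SS_tot about
the observed mean, always evaluated in the original response space even for
families fitted in log space; it can be negative for nonlinear fits worse
than the mean, and that is reported as-is. The significance threshold used
in summaries is 0.05. No multiple-testing correction is applied anywhere —
the analyses report per-comparison p-values by design.

## Regression-family search

Linear-in-parameters families are solved by ordinary least squares on their
basis expansion; power (y = a·x^b) and exponential (y = a·e^(bx)) families
are solved by OLS in log space (requiring positive response, and positive
covariates for power/logarithmic) and then scored in the original space.
The catalogue: univariate — linear, polynomial degrees 2–3, power,
exponential, logarithmic; bivariate — every non-empty subset of the nine
monomials x1^i·x2^j (1 ≤ i+j ≤ 3) together with an intercept, 511 families,
the full degree-1 subset doubling as the bivariate linear model. This is a
reproducible superset of the "try many functions" style of exhaustive
curve-fitting searches. Ranking is by raw R² (ties: fewer terms, then
name); there is no train/test split or information criterion, so at n ≈ 7–8
compartments the top fits are overfitted by construction — each fit
therefore carries its n and a Spearman validation of fitted vs observed,
and families with more terms than points are skipped rather than
regularized. Rank-deficient designs are rejected, not regularized.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
biology. Each compartment is a two-Gaussian mixture on the pI axis (an
acidic and an alkaline peak, weights per compartment, common sd 0.8,
peaks at the canonical 6.0 / 8.25), and each drawn target pI is realised as
a concrete sequence. The default ten-compartment table makes cytoplasm,
cytoskeleton, lysosome, peroxisome, er and extracellular acid-biased and
nucleus, mitochondria, membrane and golgi alkaline-biased — the qualitative
split reported for real compartment sub-proteomes — but every number in it
is a generator parameter, not a measured value.

Sequence realisation is an inverse problem against the charge model,
solved in two phases. A coarse phase gives a random neutral backbone a
protein-like ionizable content (~25% of residues) split between acidic and
basic groups so the net charge at the target pH is approximately zero
(lysine-based below pI 10.5, arginine-based above, with lysine retained as
a fine-adjustment knob where arginine carries the charge). A greedy phase
then evaluates a palette of single-residue swaps — coarse
(neutral ↔ K/R/D/E) through fine (D↔E, K↔R, His, and the choice of first
residue, which selects among the graded N-terminal pKas) — and applies
whichever brings the computed pI closest to the target, steering on an
unrounded 1e-5-tolerance pI so sub-0.001 steps remain visible. When single
swaps hit their granularity floor, paired raise+lower swaps net arbitrarily
fine steps; if a backbone's achievable-pI lattice still has a gap at the
target (rare, mostly above pI 12), the build restarts from a different
random backbone with jittered ionizable content, all derived from the one
seed. The proteome generator additionally redraws the target from the same
mixture component if a specific target/length pair remains unreachable
(~0.2% of uniform draws across the full achievable range, far fewer from
the default mixtures) — rejection sampling of achievable targets.
Everything is deterministic given the seed; there is no global random
state.

What passing end-to-end tests on this generator shows: the pipeline
recovers known compartment means, share-curve signs and regression
coefficients from data with exactly the assumed structure. What it cannot
show: robustness to real-data features the generator does not emulate —
annotation error, domain composition, signal peptides, length–pI
covariance, heavy-tailed compartment sizes.

## Problem sizes and numerical choices

- Acceptance-style checks: the pI engine is compared against an
  independent two-stage grid scan (0.01 coarse, 1e-4 fine) of the charge
  sign change; the end-to-end sign test runs 10 compartments × 2,000
  proteins in the test suite, and `scripts/acceptance.py` uses 10 × 1,200
  for the same quantity with 200 replicates of the regression recovery
  experiment — sizes chosen so each check resolves its target effect
  comfortably on a single CPU.
- Degenerate inputs are errors, not silent NaNs: empty histograms,
  zero-variance correlation inputs, all-tied rank series, rank-deficient
  designs and unreachable generation targets each raise a typed exception.
- Published experimental protein sets (lysosomal, Golgi, extra-alkaline)
  are consumed via FASTA or XLSX loaders but are not redistributed; the
  tests that check their mean pIs (6.83, 6.85) and the extra-alkaline
  count (503 at pI > 11.5) fail with a pointer until the files are placed
  under `data/experimental/`.

## Known limitations

- The charge model ignores site–site interactions and modifications; for
  phosphoproteins or disulfide-rich proteins the computed pI can be off by
  far more than the numerical tolerance.
- The redundancy screen's k-mer identity is a heuristic; it can retain
  pairs an alignment-based tool would merge (repeat-rich sequences shift
  the distinct-k-mer denominator).
- With ~7 usable compartments, the regression search's top R² is an
  optimistic, overfitted quantity; it is reported with n and Spearman
  validation rather than corrected, because raw-R² ranking is the analysis
  this package implements.
- Compartment labels are single labels; proteins genuinely resident in
  several compartments are profiled as the separate `multi` class rather
  than fractionally assigned.
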