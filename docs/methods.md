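# Methods

This note documents the models and procedures implemented in earkit, the
defaults and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical choices a maintainer should know about.

## Signal model and class assignment

Chip intensities are 16-bit scanner units (0–65535). The replicate summary
is the arithmetic mean over present replicates (missing replicates are
tolerated). Background correction is per peptide: each experiment includes a
secondary-antibody-only chip, so every peptide has its own secondary mean.
Peptides whose secondary-only mean is *strictly* larger than the IVIG mean
are removed (they bind the detection antibody directly); ties are retained.
Duplicate sequences keep the measurement with the highest IVIG mean, ties
broken by first occurrence in file order for reproducibility.

Class thresholds act on the net signal (IVIG mean − secondary mean): binding
strictly above 10,000, non-binding at or below 100, unassigned in between —
the boundary value 10,000 itself is unassigned. The in-between band is
deliberately excluded from analysis: those peptides risk wrong assignment.

The half/half split is stratified by class even though plain random sampling
would almost achieve the same balance; stratification is what makes the
printed per-class half sizes (e.g. 6,841 binders → 3,420/3,421) exactly
reproducible, with the odd peptide going to the test half. Oversampling
keeps every peptide and duplicates uniformly drawn minority peptides with
replacement until parity; undersampling drops uniformly drawn majority
peptides without replacement. All randomness flows from one explicit seed
per invocation; there is no global random state.

## Ratio PWM

Only 15-mers enter PWM construction (the matrix is 20×15 by definition);
other lengths are excluded with a warning. Frequencies use additive
smoothing, `(count + ψ) / (n + 20ψ)` with ψ = 1 by default, applied
identically to the binding and non-binding matrices — this keeps every ratio
finite and preserves the identity property (same input sets ⇒ all ratios
exactly 1). Scores are accumulated in log space to avoid underflow across
15 factors and reported on the product scale, where the classification
threshold 2.45 lives. An optional calibration mode picks the
accuracy-maximizing threshold on a training set instead. Heat-map export
orders rows and columns by average-linkage hierarchical clustering on
Euclidean distances; matrix values are never altered.

Positional propensities (row means of the ratio PWM) and the
position-independent global propensity (ratio of overall residue
frequencies) are both exposed; they answer different questions and the
position-independent form is the one meant for enrichment bar plots. With
pseudocount 0 the global propensity of a residue absent from the non-binding
set is `inf` (or `nan` when absent from both); the smoothed default avoids
this.

## Attribute representations

The eight families use window-count denominators throughout: a k-mer
frequency is its count divided by L−k+1, a distance-d pair frequency its
count divided by L−d, so values are comparable across peptide lengths.
Family defaults are k ≤ 3 for residue subsequences, k ≤ 4 for class
subsequences, and pair distances d ≤ 7; all are configurable, and the
per-family parameterization is deliberately explicit configuration rather
than the product of a tuning search.

The residue class partition is: acidic {D,E}, basic {K,R,H}, aromatic
{F,W,Y}, polar-uncharged {S,T,N,Q,C}, small-nonpolar {A,G,P},
aliphatic-hydrophobic {I,L,M,V}. The aromaticity attribute is the fraction
of {F,W,Y} residues.

Property scales (peptide mean over residues): Kyte–Doolittle hydrophobicity,
Grantham polarity, Chou–Fasman β-sheet and reverse-turn preferences, Levitt
turn occurrence, Welling antigenicity, and the two "summary factor"
attributes taken from the Atchley five-factor condensation of several
hundred amino-acid indices (factors II and V: secondary-structure and
electrostatic character). Aromaticity and acidity are indicator scales.
The registry is replaceable at run time, so any scale can be swapped by
configuration.

## Stacked ensemble

One base classifier per attribute family, trained on oversample-balanced
data; out-of-fold probabilities from a 5-fold class-stratified split form
the meta attribute vector, so no peptide is ever scored by a model that saw
it. The meta-classifier trains on those vectors either at the original class
ratio (default — the headline configuration) or oversample-balanced. Base
and meta learners default to standardized L2 logistic regression; any
scikit-learn-style probability classifier can be substituted per family.
The final label uses the canonical 0.5 probability cutoff (configurable).
Training is deterministic given the seed.

## Rule induction

The RIPPER-style learner grows rules for the minority (binding) class with
non-binding as default. Per rule, uncovered examples are split 2:1
(class-stratified) into grow and prune sets; conditions `attr < v` /
`attr ≥ v` are added by FOIL information gain until no grow-set negative is
covered (candidate cuts are midpoints between sorted unique values, capped
at 24 per attribute); pruning drops final conjunct sequences to maximize
(p − n)/(p + n) on the prune set, preferring shorter rules on ties. Rule
addition stops when a pruned rule errs on more than half of the prune set or
when a simplified MDL (rule-encoding bits plus binomial exception coding)
exceeds the best total by 64 bits. One optimization pass re-grows each rule
as a replacement and a revision and keeps the variant minimizing ordered-list
training error; a second pass changed nothing on data of the sizes this
toolkit targets while doubling induction time, so one pass is the default
(`optimize_passes` is configurable). Evaluation is strictly ordered:
first matching rule wins.

Rule summaries report, per attribute, the direction required for binding and
the percentage of *all* binding peptides correctly classified by the rules
containing that attribute, evaluated in ordered context (a peptide counts
for the rule that actually catches it, not for every rule that would match
in isolation — the alternative, context-free reading would overcount).
Within a rule an attribute votes for a direction once, with its first-grown
conjunct; a later opposite-sense conjunct on the same attribute only closes
an interval.

## Stratification and EAR types

Classifiability judging uses the interpretable logistic classifier at the
0.5 cutoff inside a 5-fold class-stratified split: each peptide is judged by
a model that never saw it, and correct judgments define the classifiable
set. Group-wise verification uses 10-fold cross-validation — partitioning
(5 folds) and verification (10 folds) are distinct fixed defaults. The
2nd degree partition repeats the procedure inside the 1st degree
unclassifiable subset.

At the sample sizes this toolkit targets (thousands of peptides rather than
tens of thousands), the stratification pipeline defaults to the k ≤ 1
interpretable attribute set (20 residue frequencies + 10 scale means):
larger subsequence vocabularies make the fold classifiers noisy enough that
peptides from the majority subpopulations leak into the unclassifiable
group and blur the partition. The per-peptide interpretable attribute
builder keeps its k ≤ 5 default for rule induction and inspection.

PWM rescue builds the ratio PWM inside the restricted subset and, by
default, evaluates at the accuracy-maximizing threshold on that same subset.
This replicates an in-set evaluation protocol; for honest generalization
estimates use the `fixed` threshold mode with a threshold chosen elsewhere —
the in-set AUC is the quantity of interest here, the threshold only sets the
operating point.

Type I EAR = binding ∩ 1st degree classifiable; Type II EAR = binding ∩
1st degree unclassifiable. Non-binding peptides receive no type, and neither
stratification nor typing ever changes a peptide's binding label. Scatter
coordinates score each peptide against the whole-set ratio PWM (x) and the
unclassifiable-only ratio PWM (y).

## Composition statistics

Epitope residues come from pre-extracted tables (structure id, residue
string); interface extraction from atomic coordinates, redundancy removal
and resolution filtering are documented curation steps of the upstream
protocol but out of scope here. Combined group frequencies are unweighted
means of the per-residue percentages — this convention reproduces the
published combined N+Q+E values (11.8% and 11.1%) from their printed
per-residue components exactly. The Type II residue group is {N,Q,E}; S and
A are excluded because they are generically enriched in protein-protein
interfaces and would inflate Type II scores nonspecifically.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes, not
the biology of any particular screen:

* 25% of assignable peptides are binders (the 3:1 class imbalance);
* binders split into a Type I majority (82%) with Y/W/F sampling weights ×3
  and N/Q/E/S/A ×1/3, and a Type II minority (18%, inside the expected
  15–20% band) with the inverted bias;
* non-binders mirror that structure: a majority with the inverted (Type-II
  like) composition and an 8% minority with Type-I-like composition. The
  minority fraction is a calibrated quantity: among aromatic-rich peptides
  the binder posterior is then ≈ 0.205/(0.205 + 0.06) ≈ 0.77, decisive
  enough that a whole-set composition classifier confidently calls
  aromatic-rich peptides binding — so its failures concentrate exactly on
  the two minority subpopulations. A larger minority (e.g. 18%) drives the
  posterior toward 0.5 and the classifiable/unclassifiable boundary
  dissolves into noise;
* net signals are log-normal per class (binders median 20,000, σ_log 0.25;
  non-binders median 30, σ_log 0.4), placing >99% of intended binders above
  10,000 and intended non-binders below 100; a 5% unassigned band (median
  1,000) populates the excluded middle; triplicates add 2% multiplicative
  noise; 5% of rows get secondary > IVIG and are removed by preprocessing;
* optional position effects put class-specific residue preferences at fixed
  positions with the preferences swapped between classes, so overall
  composition is identical while positional structure differs. The default
  weight 20 makes the informative residue ≈51% likely at its position; the
  closed-form AUC of the ideal positional score for the two-position design
  is then ≈0.95 (at weight 8 it would be only 0.82, too weak to represent a
  strong-position-signal regime).

Ground truth (class, subpopulation, artifact flag) is written separately
from the chip table so pipeline stages cannot peek.

What the generator does **not** emulate: overlapping peptide tiling of
source proteins (peptides are i.i.d.), cross-experiment batch effects,
correlated replicate noise, sequence-dependent staining chemistry, and any
relationship between a peptide's composition and its signal *strength*
beyond class membership. Passing tests on synthetic data therefore show
that the algorithms recover the structure they assume; they do not certify
performance numbers on real screens.

## Reference performance context

On the original full-scale screen (75,534 peptides, ~27k assignable), the
reported test-set AUCs were 0.884 for the stacked ensemble and 0.849 for the
PWM, with base classifiers at 0.863–0.873 — values that depend on that data
set and on an extensive attribute/algorithm tuning search not reproduced
here. They are context, not targets: at the desk scale this package tests
(n = 4,000 synthetic peptides; ~1,800 training peptides after filtering and
splitting) the corresponding quantities land near 0.85–0.87, and the
meaningful checks are structural — the ensemble not falling below its best
base classifier, the stratification paradox, propensity sign patterns, and
exact agreement with brute-force oracles.

## Degenerate inputs and numerical conventions

* ROC ties receive 0.5 credit (rank formulation); trapezoidal integration
  over the full curve, endpoints (0,0) and (1,1) always present.
* MHC score aggregation over alleles defaults to the maximum (a peptide
  presented by any allele counts as presentable); mean is available.
* Constant attribute columns are dropped with a warning before logistic
  fitting; L2 regularization keeps coefficients finite either way.
* PWM construction refuses empty inputs and mixed lengths; ratio
  construction refuses mismatched pseudocounts and zero denominators.
* Threshold calibration scans midpoints between adjacent distinct scores
  and prefers the smallest maximizer, making it deterministic under ties.
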