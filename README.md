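# earkit

Analysis toolkit for **epitope-antibody-reactivity (EAR)** measured on
high-density peptide microarrays probed with IVIG (pooled IgG from thousands
of healthy donors). Starting from raw chip signal tables, earkit labels
peptides as antibody binders or non-binders, predicts binding from sequence
with two complementary methods — a ratio position weight matrix (PWM) and a
stacked ensemble over eight peptide representations — and stratifies binders
into two recognition modes (Type I and Type II EAR) with opposite amino-acid
composition. It is written for immunoinformaticians working with linear
B-cell epitope screens who need the full pipeline to be scriptable from
Python.

## The methods in brief

**Signal filtering.** Each peptide carries triplicate fluorescence
intensities (16-bit, 0–65535) under IVIG + secondary antibody and under
secondary antibody alone. Replicates are averaged; peptides whose
secondary-only signal exceeds the IVIG signal are removed as artifacts;
duplicates keep the highest IVIG mean. The net signal
`net = ivig_mean − secondary_mean` labels a peptide *binding* (net > 10,000),
*non-binding* (net ≤ 100) or *unassigned* (in between). Assignable peptides
are split in half (class-stratified) and training sets can be balanced by
random over-/undersampling.

**Ratio PWM.** For binders and non-binders separately a 20×15 position
frequency matrix `F(a, j)` is built with additive smoothing
`F = (count + ψ) / (n + 20ψ)`, ψ = 1. Their elementwise quotient
`R(a, j) = F_bind / F_nonbind` is the ratio PWM ("epitope propensity":
R > 1 means residue *a* at position *j* is enriched in binders). A peptide
scores `S(p) = ∏_j R(p_j, j)` (computed in log space); S > 2.45 classifies it
as binding. Position-independent propensities divide overall residue
frequencies instead.

**Stacked ensemble.** Eight attribute vectors a₁…a₈ describe each peptide
(residue frequencies, frequency differences, k-mer frequencies, property
scale means, residue-class frequencies, class k-mers, residue pairs at a
distance, residue-at-offset indicators). One base classifier per family is
trained on oversample-balanced data; their out-of-fold probabilities
(5-fold CV) form the meta vector a_M(p) = [C₁(a₁(p)), …, C₈(a₈(p))] on which
a meta-classifier C_M computes the final epitope probability.

**Rules and stratification.** A RIPPER-style learner induces ordered
IF/AND/ELSE rules over interpretable attributes (k-mer frequencies plus
physico-chemical scale means), summarized per attribute as
(attribute, low/high, % of binders correctly classified). Held-out judging
(5 folds) partitions peptides into *1st degree classifiable / unclassifiable*;
binding ∩ classifiable = **Type I EAR** (Y/W/F-rich, N/Q/E-poor), binding ∩
unclassifiable = **Type II EAR** (opposite bias). Iterating inside the
unclassifiable remainder gives the 2nd degree partition, and a subset-built
ratio PWM rescues position-specific signal that composition features cannot
see (3rd degree).

**Composition statistics.** For antibody-antigen crystal structures with
pre-extracted epitope residues, per-epitope residue percentages, unweighted
averages over epitopes, combined Y+W+F vs N+Q+E frequencies and Type I/II
candidate rankings.

A synthetic chip generator (`earkit.synthetic`) emulates the statistical
structure of such a screen — 3:1 class imbalance, mirrored Type I/II
composition biases, signals straddling both thresholds, secondary-antibody
artifacts, optional position-only effects — so every stage is testable
without any external data.

## Worked example

```python
from earkit import peptide_io as pio, stratify as st
from earkit.synthetic import SyntheticConfig, generate_dataset

chip, _ = generate_dataset(SyntheticConfig(n_peptides=4000, seed=1))
labeled = pio.assign_classes(pio.preprocess_records(pio.records_from_frame(chip)))
assignable = [p for p in labeled if p.label != pio.UNASSIGNED]

part, types, feats = st.stratify_peptides(assignable, seed=5)
labels = [p.label for p in assignable]
acc_all, _ = st.groupwise_cv_performance(feats, labels, folds=10, seed=6)
acc_un, _ = st.groupwise_cv_performance(
    feats, labels, ids=part.unclassifiable_ids, folds=10, seed=6
)
frac = 100 * len(part.unclassifiable_ids) / len(assignable)
print(f"unclassifiable: {len(part.unclassifiable_ids)} of {len(assignable)} ({frac:.1f}%)")
print(f"Type I EAR: {len(types.type_I_ids)}   Type II EAR: {len(types.type_II_ids)}")
print(f"whole-set 10-fold CV accuracy:      {100 * acc_all:.1f}%")
print(f"within-unclassifiable CV accuracy:  {100 * acc_un:.1f}%")
```

prints:

```
unclassifiable: 432 of 3606 (12.0%)
Type I EAR: 685   Type II EAR: 219
whole-set 10-fold CV accuracy:      88.0%
within-unclassifiable CV accuracy:  95.8%
```

The whole-set classifier is stuck near 88% because ~12% of peptides obey
*inverted* composition rules; retrained inside that remainder, the same
classifier reaches 95.8% — the stratification paradox that motivates the
Type I / Type II distinction. Each `examples/*.py` script demonstrates one
capability (filtering, PWM scoring, ensemble prediction, stratification,
epitope composition) and prints what the numbers mean.

A thin CLI covers the same stages from a shell:

```bash
ear synth --n 4000 --seed 1 --out chip.tsv --truth truth.tsv
ear filter --chip chip.tsv --out labeled.tsv
ear pwm --train labeled.tsv --threshold 2.45 --out scores.tsv
ear train --train labeled.tsv --out model.pkl
ear predict --model model.pkl --in peptides.fasta --out preds.tsv
ear eval --preds preds.tsv --truth labeled.tsv --out report.json
```

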