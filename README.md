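# regexgp

Genetic programming over **weighted regular-expression rule lists** for
modelling a peptide sequence → phenotype mapping, plus an in-silico
**directed-evolution** screen that uses the evolved model as its oracle.

The package targets the kind of problem faced in CEST-MRI contrast-agent
design: a small curated dataset (~150 peptides of 10–13 residues, each
with one measured contrast value, MTR_asym % at 3.6 ppm) and a need to
propose new peptides with a higher readout.  Deep models are data-starved
and opaque at this scale; an evolved list of regular expressions is
trainable on ~100 sequences and every prediction is fully inspectable.

## The model

An individual is a *protein-function model*: an ordered list of up to 30
rules, each a regular expression over the 20 amino-acid letters with a
trained weight.  Patterns are genotypes — depth-≤6 binary trees in heap
layout (node *i* → children *2i+1*, *2i+2*) over the operators
concatenation, alternation `|`, `+`, `{n}`, `[...]`, `[^...]` and
grouping.

*Weight training.*  Sliding windows (2–6 residues) over the training
sequences build a **motif database**: each motif gets a class
(1 if it comes mostly from sequences with phenotype ≥ T, else 0; here
T = 12.5, the poly-L-lysine K12 gold-standard value) and the mean
phenotype of its occurrences in the winning class.  A rule's weight is

```
Final_Weight = Σ_matches ± CEST_motif × |motif|      (+ if CEST_motif ≥ T, − otherwise)
```

summed over every regex match on every training sequence that has a
database entry.  A peptide's **predicted score** is the sum of the
weights of the rules that match it, and model fitness is the Pearson r
between predicted scores and phenotypes under k-fold (k = 6)
cross-validation with per-fold database rebuilds.

*Evolution.*  Classic generational GP: tournament selection (k = 5),
one-point crossover on the rule lists (probability 0.9), two-tier
mutation at rate 0.1 (rule add/replace/delete; subtree replace/exchange/
delete and leaf growth), elitism, truncation of the doubled pool back to
the population size.  A **random-weight control mode** replaces training
with uniformly random weights in [−10, 10], perturbed at the mutation
rate — the baseline that shows what weight training itself contributes.

*Screening.*  Directed evolution refines a random library of 12-mers by
parallel single-substitution hill climbing under the model (strict score
improvement), then discards peptides whose summed per-residue
hydrophilicity is ≤ 0 (Wimley–White interface scale; positive =
hydrophilic) and reports the top 20 by score.

## Worked example

```bash
python examples/train_model.py
```

trains a model on 200 synthetic sequences whose phenotype is driven by a
planted "KS" motif and prints:

```
best fitness (CV training r): 0.926
validation r (held-out folds): 0.908
30 rules; the highest-weighted:
  (KS)+              weight      751.6
  (KSK)+             weight      189.5
  ...
```

The run recovered the planted motif: the top-weighted rule `(KS)+`
matches exactly the sequences carrying the phenotype-driving motif, and
the CV training/validation correlations (0.93/0.91) say the model
explains the synthetic phenotype almost up to its noise floor.
`examples/screen_peptides.py` continues the pipeline: after 100
directed-evolution cycles every top-20 candidate contains the planted
motif.  The other examples cover dataset statistics, the motif database,
and the hydrophilicity filter.

A thin CLI wraps the same API for shell use:

```bash
regexgp simulate --n 200 --seed 1 --out synth.csv
regexgp train --dataset synth.csv --out model.csv --seed 1
regexgp predict --model model.csv --seq QSLKQSIKKLKK
regexgp evolve-peptides --model model.csv --cycles 100 --out candidates.csv
regexgp stats --dataset synth.csv --identity --aa-freq
```

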