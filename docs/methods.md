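# Methods

## Problem setting and model

The package models a single real-valued peptide phenotype (developed
against CEST-MRI contrast, MTR_asym % at 3.6 ppm, but nothing downstream
is assay-specific) as a function of short-sequence content.  A model is
an ordered list of 1–30 rules; a rule is a regular expression with a
weight.  Prediction is deliberately coarse: a peptide's score is the sum
of the weights of the rules that match it at least once.  Match
*presence* gates a weight — match counts do not — so a rule behaves as a
learned boolean sequence feature.

Patterns are not free-form: each is rendered from a binary tree of at
most depth 6 stored in heap layout (parent *i*, children *2i+1*/*2i+2*;
63 slots), with leaves holding 1+ amino-acid letters and internal nodes
drawn from {concatenation, alternation, `+`, `{n}`, `[...]`, `[^...]`,
group}.  The depth bound caps pattern complexity and keeps matching on
10–13-mers trivially fast.  Rendering conventions: alternations and
groups are parenthesized; quantifier operands are parenthesized unless
they are a single letter or bracket class (this makes nested quantifiers
like `(K+)+` syntactically safe); a bracket operator flattens its
subtree, collecting the distinct letters of all leaves below it in
first-appearance order.  Matching is delegated to the standard
backtracking regex engine with leftmost, non-overlapping scan semantics;
empty matches cannot arise because leaves are non-empty and quantifiers
require one repetition.  A per-scan wall-clock budget (0.25 s) exists as
a guard; a scan that exceeds it is scored as non-matching for training
purposes.  On 13-residue subjects no generated pattern has approached it.

## Weight training

The motif database is rebuilt from whichever sequences are currently
"training" material.  Sequences are classed positive when their
phenotype is ≥ T = 12.5 (the poly-L-lysine K12 reference value; equality
counts as positive so the reference itself is in the positive class).
Every 2–6-residue window is a motif occurrence; per unique motif the
occurrences are counted per class, the majority class wins (ties go to
class 0, the conservative choice), and the motif's value is the mean
phenotype over the occurrences in the winning class.  Averaging over
*occurrences* rather than distinct sequences makes the build invariant
to record order.  Single residues are extracted for composition
analyses but deliberately excluded from the database: with them
included, every one-character pattern (letters, `[...]`, `[^...]`)
acquires a weight of thousands while carrying essentially no sequence
information, and evolution reliably converges to uninformative
high-magnitude rule mosaics (observed directly during development:
held-out correlations dropped from ~0.6–0.9 to ~0.0–0.2).

A rule's weight is the sum over all training sequences and all matches
of ± value × motif length, positive when the motif value is ≥ T.
Matches with no database entry (unseen, or longer than 6) contribute
nothing.  Weights are therefore deterministic given (pattern, data):
rules are independent, training is order-free and parallelizable, and
the evolutionary engine memoizes per-pattern match vectors and per-fold
weights with no effect on results.

Fitness is Pearson r between predicted scores and phenotypes.  Under
k-fold evaluation (k = 6, folds fixed once per run) the database and all
weights are rebuilt per fold from the k−1 training folds — no held-out
phenotype can leak into any weight — and the reported fitness is the
mean training-fold r, with the mean held-out r kept as an overfitting
monitor.  Degenerate correlations (either vector constant, e.g. a model
matching nothing) are defined as 0 rather than an error.

## The evolutionary engine

Generational GP with the study-standard hyper-parameters as defaults:
population 1000, 300 generations, crossover 0.9, mutation 0.1,
tournament k = 5, rule cap 30, tree depth 6, initial rule counts uniform
in 1–8 with all weights zero, ramped half-and-half tree initialization
over depths 2–6.  Each generation: the best individual is copied
unchanged (elitism), S offspring are bred from tournament winners by
one-point crossover on the rule lists (cut points that would recreate
both parents verbatim are excluded; two single-rule parents, for which
no productive cut exists, pass through as copies), offspring receive
whole-individual mutations (rule add/replace/delete) and per-rule tree
mutations (subtree replacement, node exchange within arity class,
subtree deletion with sibling promotion, leaf growth by 1–4 letters),
and the doubled pool is truncated back to S.  Fitness ties break by
parsimony (fewer rules), then position, so runs are deterministic under
a fixed seed and the best-fitness trace is monotone.

Generation-time choices the representation leaves open, fixed here as
package defaults: leaf payloads are drawn with lengths 1–3
(p = 0.5/0.3/0.2), the grow method terminates a branch with a leaf with
probability 0.45, operator sampling favours concatenation (weight 3)
and down-weights the excluding bracket (0.5), quantifiers are never
generated beneath a bracket (the bracket flattens its subtree anyway),
and `{n}` counts are uniform in 2–9.  Short literal motifs are thereby
first-class genotypes alongside composite expressions — evolved models
in this problem family are known to end up as such mixtures — and
without this bias, desk-scale populations almost never discover planted
contiguous motifs.

The random-weight control mode disables training entirely: weights are
initialized uniform in [−10, 10], offspring inherit weights through
crossover (rules created by mutation are initialized randomly), and
every rule of every non-elite individual is redrawn with probability
0.1 per generation.  Fitness in this mode is plain training-set Pearson
r.  The control is a genuinely strong baseline: selection acting on
random weight changes is itself an optimizer of the same objective,
merely a less directed one.

## Directed evolution

A library of 1000 random 12-mers (the reference-peptide length) is
refined by parallel hill climbing: per cycle each slot proposes one
substitution at a random position (resampling excludes the incumbent
residue, so every proposal is a genuine variant) and keeps it only on a
strict score improvement.  Per-slot scores are therefore non-decreasing
and plateaus are stable.  Strictness has a consequence worth knowing: a
lone motif reward with no partial credit strands any slot that would
need a neutral intermediate, so effective screening relies on the graded
sub-motif structure real evolved models possess.  After the final cycle
the hydrophilicity filter removes peptides whose summed per-residue
value is ≤ 0, and the top 20 survivors by score are reported (ties by
hydrophilicity, then lexicographically).

The packaged hydropathy scale is the Wimley–White water → POPC
bilayer-interface transfer free-energy scale, signed so positive =
hydrophilic, with ionized side chains for Asp (1.23), Glu (2.02),
Lys (0.99), Arg (0.81) and neutral histidine (0.17) — the ionization
states appropriate at the pH ~7.3 of sample preparation.  This exact
table reproduces, to two decimals, all six published per-peptide
hydrophilicity sums used as anchors in the acceptance tests.  Any other
scale can be supplied as a two-column CSV.

## Synthetic data generator

The generator emulates the statistical shape of the measured dataset —
10–13-mers, composition enriched in K/R/S/T and depleted in aromatics,
mostly <10–20% pairwise identity, phenotypes spanning ≈0–25 — while
making the sequence → phenotype map exactly known: phenotype =
clamp(baseline + Σ effect × overlapping-occurrence count + Gaussian
noise).  The default profile plants {KK:+5, SK:+4, QS:+3, EE:−4} on
baseline 8 with noise SD 1 and clamp [0, 25], sized so that ~16% of
sequences clear the 12.5 class threshold (a boundary with no members on
one side would leave weight training untested).  The recovery profile
plants a single dominant "KS" effect of +8; K and S are both common
under the composition bias, so the motif occurs in a workable ~15–20%
of sequences.

What passing on synthetic data does and does not show: the generator's
phenotype is additive, noise is Gaussian, and motifs are exact
substrings — real CEST contrast has context effects, and real motifs
may be degenerate.  Recovery tests demonstrate that the machinery can
find planted structure of the kind it searches for; they say nothing
about chemistry.

## Evaluation scale and known limitations

Tests and the acceptance script run the pipeline at desk scale
(populations 100, 20–40 generations, 150–300 sequences) rather than the
cluster scale of the original experiments (population 1000, 300
generations, 50–100 replicates); problem sizes are stated in each test.
Two behaviours observed at this scale are worth recording.  First,
trained-mode search is bimodal: a run either discovers the planted
motif (held-out r ≈ 0.9) or converges to a moderately-fit rule mosaic
(held-out r ≈ 0.1-0.2); larger populations make discovery more
reliable.  Second, the random-weight control is strong — on replicates
where both modes discover the motif structure, Pearson's scale
invariance makes their held-out correlations nearly identical, so
paired per-replicate comparisons of the two modes include effective
ties decided by noise.  The mean advantage of weight training over the
control reproduces clearly (≈0.84 vs ≈0.71 held-out r across 10
paired replicates under the recovery profile), but per-replicate
dominance strong enough for a 10-pair sign test at the 0.05 level
(≥9/10 wins) is beyond the effect size at this scale; the corresponding
acceptance test records this honestly rather than relaxing its bar.

Other limitations: no multi-objective optimization (e.g. fitness vs
parsimony Pareto fronts); no fuzzy motif lookup in the database (the
regex layer is the only source of flexibility); identity is positional,
not alignment-based, and uses the longer sequence as denominator; the
`+` quantifier is unbounded even though matches longer than 6 residues
can never score during training.
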