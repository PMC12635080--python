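# Methods

`g4scan` is a desk-scale toolkit for RNA G-quadruplex (rG4) analysis: it
detects and classifies rG4 motifs from sequence, trains a miniature masked
language model to score rG4 formation probability, quantifies the effect of
single-nucleotide variants on that probability, attributes predictions to
flanking k-mers, tests rG4 flanks for RNA-binding-protein motif enrichment,
and runs the population-genetic comparisons used to detect negative
selection on rG4-disrupting variants. Every stage runs end to end on seeded
synthetic data with known ground truth.

## The rule engine

A canonical rG4 is four runs of at least three guanines separated by loops
of 1–7 nt, (G≥3 N1–7)×3 G≥3. Classification is hierarchical over eight
stability-ranked classes:

1. canonical — four G≥3 runs, loops 1–7 nt;
2. long loop — as canonical, but exactly one loop of 8–12 nt;
3. bulges — one of the four runs carries a single-nucleotide bulge
   (G1–2 · X · G1–2 with ≥3 G in the bulged run), other runs G≥3;
4. two-quartet — four G≥2 runs, loops 1–9 nt;
5. potential G-quadruplex — four G≥2 runs with relaxed loops (1–30 nt) and
   overall G content ≥ 40%;
6. potential G-triplex — three qualifying G-runs with relaxed loops and
   G ≥ 40%;
7. G-rich — G ≥ 40% only;
8. unknown — none of the above.

When a sequence matches several patterns it receives the most stable
(lowest-rank) class. All loop bounds, the bulge size and the G-content
threshold are configurable (`PatternConfig`); the defaults above follow the
classification scheme this hierarchy is standard under. Two choices the
scheme leaves open are made explicit: G content is computed over the full
input sequence (not the motif window), and ties between spans of the same
class resolve to the leftmost span.

Matching operates on the list of *maximal* G runs rather than on a raw
regular expression, so a long run is never split to fabricate an artificial
loop, and loops never begin or end inside a run. Candidate windows are
consecutive qualifying runs; skipping a qualifying run can only lengthen a
loop, so consecutive windows are sufficient for existence.

## Window scorers

Two reference scorers provide raw-scale baselines and sanity anchors.
G4Hunter scores each base +min(run, 4) within a G run, −min(run, 4) within
a C run, 0 otherwise; a window's score is the arithmetic mean of its base
scores and a sequence's score is the maximum over 60-nt sliding windows
(the whole sequence when shorter). cGcC is the ratio of weighted
consecutive-G to consecutive-C content per window; the run-weight table is
configuration (default: per-base weight 10×min(run length, 4)) with a
pseudocount of 1 on both numerator and denominator, which makes a G↔C swap
invert the score exactly and scores a G/C-free window 1.0. Binary
"detected" calls use thresholds of 0.9 (G4Hunter) and 4.5 (cGcC) on the
max-aggregated score. Probabilistic scorers (the rule oracle, the
fine-tuned model) expose `predict_prob` in [0, 1]; baseline scales are
never unit-converted.

## The miniature language model

The encoder is a BERT-style bidirectional transformer over overlapping
6-mer tokens (vocabulary 4^6 k-mers + 5 specials), with learned token and
position embeddings, post-layer-norm residual attention and GELU
feed-forward blocks. Sequences tokenize to L−5 content tokens, capped at
510 per chunk so a [CLS]…[SEP]-wrapped chunk fits a 512-token input;
longer token lists split into consecutive non-overlapping chunks.

It is implemented directly in numpy with hand-written analytic gradients,
verified against finite differences in the test suite. That choice keeps
the gradient of the output with respect to the input token embeddings
exact and inspectable, which the attribution module depends on.

Pre-training is standard masked-language modelling: 15% of content tokens
are selected (80% → [MASK], 10% → random k-mer, 10% unchanged), and the
loss is the mean cross-entropy at selected positions (materialized only at
those positions for speed). Fine-tuning adds a softmax head on the [CLS]
state: 2 epochs for the binary rG4 task, 5 for the 8-class subtype task,
learning rate 2e-4, batch 32, Adam. Desk-scale defaults are 2 layers,
2 heads, hidden size 64, ≤5k pre-training steps; the full-scale
values (6 layers, 6 heads, effective batch 250, 200k steps) are
expressible in `ModelConfig` but are deliberately not the defaults — the
package exercises the mechanism, not trained weights. All stochastic
stages take a seed and are bit-reproducible.

`G4merClassifier` wraps fine-tuning behind a scikit-learn-style surface
(`fit`, `predict_proba`, `get_params`/`set_params`, fitted attributes with
trailing underscores) so it composes with sklearn model selection.

### Dataset construction

Positives are experimentally-detected (here: simulated) rG4 sequences,
deduplicated, extended with transcript flanks to at most 70 nt with the
motif centered (left flank takes the extra base; windows truncate at
transcript ends without padding). Negatives are matches of the relaxed
putative-G4 pattern G2+(N1–30 G2+)×3 in rG4-free background transcripts,
centered in windows whose lengths are drawn from the empirical
positive-length distribution; at most 1200 negatives are sampled (seeded)
per 10-nt match-length bin over 10–60 nt, and a background that cannot
supply a 1:1 ratio produces a warning with the shortfall, not an error.
Multiclass labels delegate to the rule engine. Cross-validation is
stratified k-fold (k=10 by default) reporting accuracy, ROC-AUC and PR-AUC
per fold and mean; multiclass AUCs are macro one-vs-rest.

## Variant effects (ΔG4mer-style delta scores)

A variant's delta score is mutant minus wild-type prediction probability,
both computed on the identical 70-nt window centered on the variant
(clipped at transcript ends). Two published threshold schemes are
first-class and named in every record: the gnomAD-style scheme (breaking:
wild-type > 0.7 and mutant < 0.3; non-breaking: wild-type > 0.7 and
|delta| ≤ 0.02) and the biobank-style scheme (breaking: wild-type > 0.5
and delta ≤ −0.2; forming: wild-type < 0.5 and delta ≥ +0.2). Records in
neither band are kept with category OTHER rather than dropped. When one
variant maps to several transcripts, the most disruptive (minimum-delta)
record is retained, ties resolved by transcript id. The false discovery
rate of a scorer is estimated on an rG4-free background as the fraction of
sliding windows (70 nt, stride 10) scoring above 0.7 — windows, not
transcripts, form the denominator.

## Attribution and perturbation

Integrated gradients run along straight-line paths in token-embedding
space from each of three baselines to the input, with a 200-step midpoint
Riemann sum; per-token attribution is the path-averaged gradient times the
embedding displacement, summed over embedding dimensions and averaged over
baselines. Baselines are the three non-rG4 sequences whose representations
(mean final hidden state) are nearest the coordinate-wise median
representation of the baseline class; length mismatches are resolved by
trimming or repeat-cropping the baseline token sequence. Tokens
overlapping the rG4 motif are zeroed to focus on flanks. The completeness
axiom (attributions sum to f(input) − f(baseline)) is exact for linear
models and holds to well under 1% on the trained model at 200 steps.

Flank-token significance uses a two-sided t-test of each k-mer's
attribution values (pooled across sequences) against a seeded random
reference set of non-motif token attributions, Benjamini-Hochberg adjusted
at q < 0.05; groups that are identically constant short-circuit to p = 1.
Nucleotide/2-mer/3-mer projections take the maximum attribution over the
significant 6-mers fully containing each position, within ±20 nt of the
motif, zero inside it.

The perturbation map substitutes each flank G with C and each C with G,
one at a time, within 60 nt of a canonical motif in sequences scoring
above 0.7, and aggregates mean delta by mutation type and position
relative to the motif. A caveat discovered with this synthetic design: the
relaxed-regex negative recipe makes negatives G-rich, so on the synthetic
task extra flank guanine pushes *toward* the negative class and the
G→C/C→G direction seen on models trained on experimental data is not
reproduced by the miniature model; the tests therefore verify perturbation
directionality against a G4Hunter-backed scorer, where flank guanines are
stabilizing by construction.

## Motif enrichment in rG4 flanks

Sequences containing a canonical motif split into forming (score > 0.7)
and non-forming (score < 0.3) groups; scores in between are excluded. The
two flanks of one motif form a single counting unit. Each position
probability matrix (MEME minimal input; T read as U) is scanned by
log-odds against a uniform background with pseudocount 1e-3; a unit has
the motif if any offset reaches the score threshold at p < 1e-4 under the
exact null, computed by dynamic-programming convolution of the per-column
score distributions on a 1e-3 discretization grid shared with the scanner.
Two edge rules: a hit always requires a strictly positive log-odds score
(a background-equal matrix can never hit), and matrices too short to reach
p ≤ 1e-4 (best case 4^−length) fall back to requiring the best achievable
score. Enrichment per motif is log2((forming fraction + ε)/(non-forming
fraction + ε)), ε = 1e-6, with a one-sided Fisher exact test on the 2×2
unit-count table, BH adjustment across motifs, and a report filter of ≥5
total hits, q < 0.05 and log2 fold enrichment > 1; the full table with
filter flags is always returned.

## Selection statistics

Variant tables are tidy DataFrames (documented column dictionary in the
module docstring). The battery: a call-rate filter keeping variants with
allele number ≥ 80% of the sequencing maximum (152,312); constraint
matching that bins one group by its own constraint-Z quartiles (ties to
the lower bin) and draws exactly the same per-bin counts from the other
group without replacement, erroring on an unfillable bin; one-tailed
Kolmogorov-Smirnov (or Mann-Whitney) tests of "breaking MAFs
stochastically smaller"; the fraction of rare variants (MAF strictly
< 0.1%); short/long rG4 stratification (≤22 nt vs ≥28 nt, with the ≥31 nt
alternative bound); equal-width raw-CADD bins with mean ± SD of delta;
chi-square tests on pairs of subtype count vectors; Welch's ANOVA with
Games-Howell post hoc (or Kruskal-Wallis with a hand-implemented Dunn test
and BH adjustment — the two adjustment styles are never mixed) for
delta-by-subtype contrasts; and a pathogenicity contrast combining a
one-sided Mann-Whitney test (pathogenic deltas more negative), the fold
enrichment for pathogenicity among strongly disrupting variants
(P(pathogenic | delta ≤ −0.5) / P(pathogenic) over all scored rG4-region
rows — the baseline set is configurable), and a one-sided binomial tail
test of the pathogenic count in the disrupting subset.

## Synthetic data

Generators are pure functions of (parameters, seed). Transcripts draw
i.i.d. bases at a requested GC content (default 0.5; a first-order Markov
option exists for harder LM tasks) and plant one motif sampled from the
target subtype's grammar, with loops drawn from {A, U, C} so planted runs
stay maximal. Accidental canonical motifs in the background are mutated
out, and a plant whose extracted 70-nt window does not classify as
intended is re-rolled, so planted canonical motifs classify canonical for
100% of plants and motif-free transcripts carry no canonical motif at all.
Variant tables place breaking variants on interior guanines of planted
runs (which provably destroys the run) and neutral variants on A/U bases
at least 10 nt from the motif; allele frequencies are Beta-distributed —
breaking Beta(0.3, 30) vs neutral Beta(0.5, 30) under the selection
regime, both Beta(0.5, 30) under the null — with allele numbers uniform in
[0.75, 1]×152,312, standard-normal constraint Z, and a +2 mean raw-CADD
shift for breaking truth. PWM sites are sampled per column and written
into flank sequences at per-sequence rates (0.4 forming vs 0.05 background
in the recovery analyses).

What the generator does *not* emulate: read-level rG4-seq signal,
transcript expression structure, linkage disequilibrium, flank-sequence
biology coupled to rG4 formation, and real constraint/CADD correlations.
Green tests therefore demonstrate that the machinery is correct and
calibrated on data with known truth — not that the miniature model matches
published benchmark numbers on experimental datasets.

## Problem sizes and numerical choices

The default study conditions are 2000 canonical positives (transcripts of
200–400 nt) with negatives mined from 900 motif-free background
transcripts (600–1000 nt), ~150 MLM pre-training steps on unlabeled
≤70-nt domain sequences (a featureless i.i.d. background corpus carries no
learnable token statistics, so pre-training uses sequence with rG4
structure, as transcriptome pre-training does), 2 fine-tuning epochs, 200-replicate null-calibration runs at
~200 variants per group, 2000 per group for the selection-power check, and
50 replicates of the planted-PWM recovery at n=200 per group. Tolerances:
IG completeness within 1% relative error at 200 steps (exact to 1e-8 on
linear surrogates); enrichment p-values exact to enumeration; MLM loss
compared against the uniform baseline log(4101). Degenerate inputs are
handled explicitly: constant groups short-circuit omnibus tests to p = 1,
empty subtype categories are dropped with a warning, a motif longer than
its window returns the motif with a truncation flag, and zero-variance
t-test groups shortcut to p = 1.

## Known limitations

The miniature model's absolute scores are not calibrated probabilities of
physical rG4 formation; only orderings and deltas are meaningful at desk
scale. The rule engine reports one best motif span per sequence (no
exhaustive multi-locus enumeration). Genomic-to-transcript projection is
out of scope — variants arrive in transcript coordinates or with a
precomputed mapping table. Multi-nucleotide and phased variants are not
supported.
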