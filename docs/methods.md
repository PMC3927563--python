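# Methods

`promoterminer` classifies fixed-length DNA segments as promoters or
non-promoters from sequence-derived descriptors alone, and — more to the
point — identifies *which* descriptors carry the discriminative signal.
This note records the model, the numerical conventions, and the design
choices made where the procedure was genuinely open.

## The descriptor vector

Every sequence over {A, C, G, T} is mapped to 167 numbers:

* **P1–P3 — physicochemical averages.** Sequence means of per-nucleotide
  absorption maximum (nm, pH 7.0), molecular weight (g/mol) and molar
  absorption coefficient: A = (259, 491.2, 15200), C = (271, 467.2, 9300),
  G = (253, 507.2, 13700), T = (267, 482.2, 9600).  For the 20-nt
  reference sequence `CATAGCCATTGCATGACCCG` (5 A, 7 C, 4 G, 4 T) the
  absorption-maximum average is 263.6 nm; the same arithmetic gives
  484.2 g/mol and 11715 for the other two rows.
* **P4–P9 — entropy density profile.** With nucleotide frequencies q_i:
  the Shannon entropy D_EH = −Σ q_i log₂ q_i (bits, 0·log 0 := 0), the
  sum of squares D_EQ = Σ q_i², and four entropy fractions
  D_Ei = −q_i log₂ q_i / D_EH.  The fractions are base-invariant; on a
  homopolymer (D_EH = 0) they are defined as 0.
* **P10–P13 — composition** q_A, q_T, q_C, q_G as fractions (not ×100;
  the downstream [0, 1] scaling makes the convention immaterial, but it
  is fixed for reproducibility).
* **P14–P19 — transitions.** For each unordered pair {α, β}, the percent
  of adjacent positions holding α,β in either order, out of L − 1 pairs.
* **P20–P39 — distributions.** For each nucleotide with c > 0 occurrences
  at 1-based positions pos₁..pos_c: the chain-length percentages
  pos₁/L·100 and pos_⌈p·c⌉/L·100 for p ∈ {0.25, 0.5, 0.75, 1}.  An absent
  nucleotide contributes five zeros (the convention is otherwise
  undefined).  The ⌈p·c⌉ index convention reproduces the reference
  sequence's A-values (10, 20, 40, 65, 80).
* **P40–P167 — discriminative 4-mers.** Each of the 256 4-mers is scored
  on the *training* classes as |f_ω/Σf − F_ω/ΣF| (overlapping,
  strand-specific counts; promoter segments are already TSS-oriented).
  Scores are linearly mapped to integers in [0, 1000] and the 128
  top-ranked motifs (ties broken lexicographically for stability) become
  descriptors.  The per-sequence value of a selected motif is its
  overlapping occurrence count divided by L − 3, keeping features
  comparable across lengths.

All features are min-max scaled to [0, 1] on the training matrix;
test-time values are clipped and constant columns map to 0.

## Feature mining

Subset selection is a wrapper search: a chromosome holds 167 binary
feature genes plus two 4-bit genes indexing the SVM hyperparameters
(γ, C) into {2⁻⁷ … 2⁸}; fitness is stratified 10-fold CV accuracy of the
RBF SVM on the selected columns (instance-weighted: total correct / n),
with folds derived from the run seed and values memoized per chromosome.

The search is *inheritable*: for each cardinality r from r_start to
r_end the population carries exactly r ones (asserted after every
operator); the stage's best is recorded and every individual then flips
one random 0-gene to 1 to seed stage r + 1.  Full-scale defaults are
population 20, r = 30..100, 60 generations per stage, p_s = 0.2,
p_c = 0.8, p_m = 0.05 (the selection/crossover/mutation fractions are
conventional wrapper-GA values; all are configurable).  Within a
generation: ranking selection replaces the worst ⌊p_s·N⌋ by copies of the
best ⌊p_s·N⌋; orthogonal-array crossover recombines ⌊p_c·N⌋ parents; swap
mutation hits ⌊p_m·N⌉ individuals.  The current best individual is
excluded from crossover and mutation, so the best fitness is
non-decreasing within a stage.

**Orthogonal-array crossover.** The positions where two parents differ
are grouped into at most seven contiguous factors; an L8 two-level array
enumerates eight candidate children taking each factor wholly from one
parent or the other.  Candidates are repaired to exactly r ones by
random balanced flips and evaluated; per-factor main effects (mean
fitness at each level) compose one child from the better level of every
factor, while the second child is the best evaluated array row.
Parameter genes recombine by one-point crossover on their 8-bit
concatenation; array candidates are evaluated with the second child's
recombined parameter genes and the composed child carries the first's.
Orthogonal arrays are built by the Walsh/parity construction (row i,
generator column c: parity of popcount(i & c)); factors are assigned to
the p basic columns first, then the all-XOR column, then remaining
columns by descending popcount.  This makes ≤ p factors a replicated
full factorial (exact main effects) and p + 1 factors the standard
resolution-IV half fraction.

**Consensus over runs.** Because the search is stochastic, R independent
runs (seeds spawned from the master seed) are aggregated: Af_j counts
the runs selecting descriptor j; a run's mass Σ_j Af_j·af_j^k weights its
selections by their cross-run frequency, and its ratio divides that by
AF = Σ Af_j.  The consensus solution is the most accurate run among
those whose ratio exceeds the mean (tie → lower run index; if no run
exceeds the mean, the global fitness maximum).  The unweighted mass
Σ_j af_j^k would make every ratio ≈ 1/R and could never discriminate
runs, which is why the frequency-weighted form is used.

**Rank-based-selection baseline.** Features are ranked by grid-searched
single-feature SVM CV accuracy; the top 100 are pooled, the top 30 seed
a greedy forward selection that adds the accuracy-maximizing feature up
to size 100.  (C, γ) for the greedy stage are grid-searched once on the
seed set — a per-step grid would cost ~70·100·256 CV fits for no
qualitative change in the baseline.

## Classification and evaluation

The final model is an RBF SVM on the masked, scaled matrix.  The (C, γ)
grid is the exhaustive 16×16 powers of two; ties go to smaller C, then
smaller γ.  Reported measures are ACC, SN, SP and MCC with the standard
numerator TP·TN − FP·FN and MCC := 0 on a zero denominator.  The
evaluation harness splits sequences into stratified training and
independent-test halves and fits the k-mer table and scaler on the
training half only — the motif ranking is label-dependent, so fitting it
on all data would leak test information.  Fixed-subset baselines use the
36 global descriptors or the 128 4-mer descriptors without selection.
Persisted models store the k-mer table's content hash and refuse to
predict against a tampered or mismatched table.

## Rules and certainty grades

Interpretable rules come from a binary decision tree (entropy criterion,
default depth ≤ 4 and ≥ 10 instances per leaf, matching the shape of
short published rule lists) grown on the mined subset of the scaled
matrix.  Each root-to-leaf path is a rule of "≤ t" / "> t" conditions
(boundary values take the ≤ branch); its certainty grade is the Laplace
leaf confidence (correct + 1)/(covered + 2), strictly inside (0, 1).
Rules are ordered by descending CF, applied first-match-wins with the
majority class as default, and summarized by cumulative prefix accuracy
in which uncovered instances count as incorrect.

## MED factor analysis

A feature's main-effect difference is estimated from a two-level
orthogonal design whose factor levels are inclusion/exclusion of the
feature: each row is scored by CV accuracy of the SVM on the included
columns (an all-excluded row scores chance, 0.5), and
MED_j = |mean fitness including j − mean fitness excluding j| × 100
percentage points.  The smallest L_{2^p} with 2^p − 1 ≥ m factors is
used; main effects from the fraction equal the full 2^m factorial's
exactly when interactions vanish, and in practice agree closely when
main effects dominate.  With several strongly redundant features the
accuracy response saturates and interaction aliasing can shift MED by a
few points — the full-factorial cross-check in the test suite therefore
uses a mixed informative/noise design in a moderate-effect regime, and
users ranking heavily redundant subsets should treat small MED gaps as
noise.

## Synthetic data

The generator emulates the *shape* of promoter benchmarks: fixed-length
(default 252 nt) two-class sets with i.i.d. class-specific backgrounds
(defaults GC 0.55 in positives vs 0.50 in negatives, a mild promoter GC
enrichment), elevated A probability (+0.3) in the first 20 positions of
positives (so the first-A-position descriptor discriminates, mirroring
the dominant signal reported for real human promoters), optional planted
4-mers, and an optional period-3 composition modulation caricaturing
CDS-derived negatives (off by default).  It does **not** model real
promoter biology — no CpG islands, TATA-box grammar or nucleosome
signals — so passing recovery tests demonstrates that the machinery
finds the signals it is pointed at, not that real promoters are
predictable at the published accuracies.  The Gaussian feature-matrix
generator plants `n_informative` columns shifted by `effect` standard
deviations between classes, min-max scaled.

## Problem sizes and numerical choices

Tests and examples run the GA at reduced scale (population 10, 5
generations per stage, cardinalities 5–15, 3 runs on 200×50 matrices),
sizes at which one mining ensemble completes in about a minute while
still exercising every operator; full-scale settings remain the
defaults of `IGAConfig`.  The planted-recovery experiment uses effect
0.6 so that no small subset saturates the CV fitness — recovery then
requires assembling the planted set, which is the property worth
testing.  Motif-ranking checks isolate the motif channel (equal
backgrounds, no leading-A boost) so the planted 4-mer is the only
class difference.  Descriptor computations are exact rational/float
arithmetic checked against naive position-loop oracles to 1e−9;
normalized k-mer scores round half to even via numpy.

## Known limitations

* The GA evaluates thousands of CV fits; at full scale on real-sized
  data a run is hours of CPU — the implementation memoizes within runs
  but does not parallelize.
* Rule induction is a single entropy tree, not a boosted or pruned
  commercial rule learner; thresholds and grades on real data will
  differ from published rule lists even at equal accuracy.
* MED values inherit CV noise and fractional-design aliasing (above).
* Descriptors are defined only over {A, C, G, T}; lenient FASTA loading
  drops other symbols rather than modelling ambiguity codes.
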