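# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical decisions that were genuinely open.

## Profile HMMs

A profile is estimated from a multiple alignment of the positive training
set. Columns with at least 50% residue occupancy become match states — the
conventional occupancy rule; at exactly 50% the column is a match state.
Match and insert emissions are pseudocounted column frequencies (Laplace
weight 1.0 per residue by default); transitions are pseudocounted counts of
the observed per-row state paths in the plan7-like topology M→{M,I,D},
I→{I,M}, D→{D,M} (no I↔D edges, so an inter-match region containing
residues is attributed to the M→I…I→M path). The null model is the
alignment-wide residue frequency.

Scoring is **local Viterbi in bits**: the model may attach at any match
state and detach from any match state at zero cost, and flanking residues
emit at null frequency, contributing exactly 0 bits. This mirrors the
default local behaviour of standard search tools while keeping the path
space small enough to verify by exhaustive enumeration (the test suite and
the validation module check equality for all toy profiles with ≤ 4 match
states against sequences of ≤ 6 residues). Best-path (Viterbi) scoring was
chosen over the forward algorithm because it is deterministic and
oracle-checkable; forward/posterior decoding is out of scope. Unknown
residues (X, B, Z, J…) emit at the null frequency and contribute 0 bits —
neutral handling of ambiguity. Scores are finite for every input because
all probabilities are pseudocounted away from zero.

A column-vectorized implementation of the same recurrence (the in-column
delete chain is a prefix scan) is used for scoring; the loop implementation
with traceback serves the FP-alignment step and is tested equal.

## Threshold calibration and emission modification

Training sets are subgrouped by Markov clustering on a cosine-similarity
graph of 3-mer count vectors (inflation 2.0, expansion power 2, tolerance
1e-6, ≤ 100 iterations; clusters read off as connected components of the
converged attractor matrix). MCL parameters follow common practice; the
similarity measure is a free choice since only relative within/between
similarity matters for subgrouping.

The discrimination threshold of a profile is selected by n-fold
cross-validation (default 5 folds, seeded shuffle + round-robin assignment,
so every positive appears in exactly one test fold). For each fold a
profile built from the remaining positives scores the held-out positives
(TP scores) and all negatives (FP scores); MCC is evaluated at every
observed score, averaged across folds, and the threshold is the **midpoint
of the score interval bracketing the maximum** of the fold-averaged MCC
curve. Ties are broken toward the higher interval, favouring specificity.
A family whose maximal fold-averaged MCC falls below 0.5 is flagged
non-discriminative.

Emission modification estimates per-match-state residue frequencies from
the false positives — negatives scoring above the unmodified threshold,
aligned to the profile by their Viterbi match-state paths (no external
aligner) — and replaces the match score log₂(p_TP/p_null) with
log₂(p_TP/p_FP). FP frequencies are shrunk toward the null with a
Dirichlet prior of mass 20 × pseudocount weight distributed in proportion
to the null: with no FP evidence at a state the modified score reduces
exactly to the base score, and sparse, unrepresentative FP sets cannot
destroy the profile. The threshold is recalibrated by re-running the
cross-validation with per-fold modified scorers.

*Limitation.* When the true and decoy families are extremely close (both
diversified ~10% around ancestors themselves only ~10% apart), the
log-ratio scores flatten at the many shared positions and local attachment
loses positional context; discrimination can degrade. At the study
condition examined by the validation experiments (decoy-family ancestor at
30% divergence) both scorers separate perfectly and the modified profile's
FP count at matched 90% sensitivity never exceeds the base profile's.

## Functional profiling

Reads are translated in all six frames with the universal code; stop codons
split translations into fragments (rather than truncating at the first
stop), maximizing usable fragments from random read windows, and fragments
shorter than 25 residues are discarded. Codons containing N translate to X
and are never stops. Fragment identifiers carry the source read, frame
(+1..+3/−1..−3), and 0-based half-open coordinates on the read's forward
strand.

Equal-depth subsampling draws records uniformly without replacement
(depth = smallest sample by default), keeping original record order;
samples already at depth pass through untouched.

A sequence contributes at most one count per gene (best subgroup wins,
each subgroup carries its own threshold), and a read counts once per gene
even when several frames pass — otherwise overlapping frames of one read
would inflate counts. Counts, not presence/absence, populate the
occurrence matrix because the downstream similarity works on (transformed)
abundances. Zero-total gene columns are dropped and logged at assembly.

## Community statistics

Abundance matrices are log₁₀(x+1)-transformed by default; environmental
tables use per-column transforms (sqrt, log, exp — "exponential" is read
literally as eˣ) chosen to reduce collinearity before a z-scored PCA.

Bray–Curtis similarities are expressed on the 0–100 scale. A pair of
all-zero samples has no defined similarity and is reported as 0 with a
warning. ANOSIM ranks all n(n−1)/2 dissimilarities ascending with midranks
for ties (the standard rank-statistic convention) and evaluates
R = (r̄_B − r̄_W)/(M/2); significance comes from T random label
permutations (default 999; 199 in the bulk simulation experiments), never
enumerating, with the +1 terms guaranteeing a valid level — the smallest
attainable significance is 1/(T+1). SIMPER averages per-pair contributions
over all cross-group pairs; its per-pair sum equals 100 − S_jk by algebra,
which the validation experiments confirm to 1e-9. The SD in the
discrimination ratio δ̄/SD is the population SD over pairs; a zero SD with
positive contribution reports an infinite ratio sentinel.

NMDS minimizes Kruskal stress-1 with isotonic (PAVA) disparities and a
Guttman majorization update, step-halving any update that would increase
the nonmetric objective so stress is non-increasing within a restart;
default 20 seeded restarts, 2 dimensions, 300 iterations. **Tie treatment
is secondary** (tied dissimilarities share one disparity). Primary ties
were considered and rejected: they leave tied blocks unconstrained, so a
degenerate all-tied input (four mutually equidistant points) reaches zero
stress trivially, which defeats stress as a diagnostic; under secondary
ties that configuration correctly retains positive stress while
configurations with distinct dissimilarities are unaffected.

## Molecular evolution

Phylogenetic spread of a gene is the mean patristic distance over all
unordered pairs of genomes carrying it; genes in fewer than two genomes are
reported undefined rather than erroring. Patristic distances are computed
from root-path depths and lowest common ancestors on the parsed tree;
simulated trees carry an independent truth matrix computed by path
summation over the generator's own edge list, and the two agree to 1e-8 on
random trees (newick branch lengths are written at 10 decimals so parsing
round-off stays below that).

Pairwise dN/dS uses the Nei–Gojobori (1986) counting method: synonymous
site fractions per codon position exclude changes into stop codons from
the denominator, so S + N = 3 × (comparable codons) exactly; differences
average over all minimal mutational pathways, excluding pathways through
stops (if every pathway is blocked, all pathways are used rather than
discarding the codon); proportions are Jukes–Cantor corrected,
d = −(3/4)·ln(1 − 4p/3). ω is undefined when dS = 0 or a proportion
reaches the correction's boundary (p ≥ 3/4); undefined pairs are excluded
from the gene mean and counted. A counting estimator was chosen over
maximum-likelihood codon models because it is self-contained and
exhaustively checkable (pathway counts for all 2- and 3-difference codon
pairs are verified against brute-force enumeration); the classification
boundary (ω vs. 1) is what the selection calls use. The class is positive
when the gene's mean ω > 1, purifying when < 1.

The codon simulator is Goldman–Yang-style: uniform frequencies over the 61
sense codons, transition/transversion ratio fixed at 2, single-nucleotide
changes only, nonsynonymous rates multiplied by ω, matrix scaled to one
expected substitution per codon per unit branch length. NG86 on data
simulated this way recovers mean ω within ±25% at ω ∈ {0.2, 1, 3} (300
codons, branch length 0.3, 50 replicates) with rank order preserved; the
known mild downward bias at high ω (κ ignored in site counting) stays
within that band.

## Synthetic data: what it emulates, what it does not

Protein families evolve by substitution only, so the true alignment is the
identity column map — this removes any aligner dependency and makes
alignment-conditional steps exactly testable. Real families have indels;
nothing here exercises gap handling beyond what gapped training alignments
provide. The `related_family` decoy mode generates a *coherent* second
family — a decoy ancestor at `divergence_decoy` from the true ancestor,
members diversified around it at the family's own divergence — emulating
the homologous-fold, different-function situation that motivates negative
training. (An earlier draft drew each decoy independently from the true
ancestor; that produces an incoherent cloud with no conservation pattern of
its own, which no FP-based modification could exploit.)

Genome collections draw per-gene member counts from a negative binomial
(mean/dispersion parameterization) — overdispersion is the realistic
stress case for Bray–Curtis on log counts. Defaults: baseline mean 10,
dispersion k = 5 (variance μ + μ²/k), 2 groups × 8 samples, 20 genes, a
handful of shuffled background decoys per sample. Reads are uniform random
substrings of back-translated genomes with random strand and deliberately
unequal per-sample counts. One global seed expands to per-component child
seeds by fixed arithmetic (`(seed·1000003 + k) mod 2³¹`), so partial reruns
reproduce byte-identically.

*What passing tests show — and a known shortfall.* Under these defaults,
planted 4× effects are always detected by ANOSIM (100/100 datasets at
T = 199), but ranking *all five* planted genes into the SIMPER top 7 by
δ̄/SD succeeds in only ~75–80% of datasets: with k = 5 a planted gene's
realized counts in the 8 affected samples occasionally sit near baseline,
collapsing its ratio. This is a property of the chosen noise regime, not of
the SIMPER implementation (the per-pair decomposition is exact); milder
overdispersion or more samples per group would raise the rate, and the
log transform is already the most favourable of the supported transforms
for this ranking (log > sqrt > raw in recovery). Real occurrence data adds
detection noise on top of count noise, so recovery rates on real data
should be read as upper-bounded by these synthetic ones.

## Pipeline

A run chains calibrate → scan → matrix → transform → Bray–Curtis → ANOSIM
(global + pairwise) → SIMPER → NMDS, with optional PCA (when an
environmental table is given) and phylogenetic spread / dN/dS (when a tree
or CDS directory is given). SIMPER runs only for group pairs whose pairwise
ANOSIM significance is ≤ 5%. Configuration is a YAML file; every stage
appends a JSON event (inputs, sizes, seeds) to `events.jsonl`, and reruns
with the same config and seed are byte-identical. ANOSIM and SIMPER are
skipped with a logged notice when group labels are absent or incomplete.

## Problem sizes in the validation experiments

The distributional experiments use 500 null datasets (type-I error), 100
planted datasets (recovery), 50 simulated families (calibration benefit),
50 codon-pair replicates per ω, 100 random matrices (decomposition
identity), and 100 random trees (patristic truth); oracle equivalences are
exhaustive over their stated domains (toy profiles ≤ 4 match states ×
sequences ≤ 6 residues; all 2- and 3-difference sense codon pairs). The
full test suite runs in about half a minute on one CPU.
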