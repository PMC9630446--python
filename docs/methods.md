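# Methods

## Coordinates and input formats

Variant positions are 1-based in each protein's own full-length numbering.
A per-member *offset* — the full-length residue number of the first residue of
the aligned construct — converts to construct-local numbering; alignment
columns (1-based) are the shared coordinate system across paralogs. Construct
bounds are always taken from the offsets config rather than hard-coded,
because family members differ in construct length. Coordinate maps are strict
bijections on non-gap positions (round-trip identity is property-tested);
when the reporting reference is gapped at a column, display numbering falls
back to the nearest preceding reference residue with a `+` suffix.

Variant tables are TSV/CSV with a mandatory header; canonical columns are
`protein_id, position, wt_aa, mut_aa` plus attachments
(`activity_me0, activity_me1, activity_sd, fathmm, polyphen2, opai,
fi_score, vc_score, vs_score, ddg`, physico-chemical deltas, `blosum62`).
Alignments are FASTA or Clustal (`.` normalized to `-`); the sidecar config
is YAML/JSON mapping `protein_id -> {clade, offset}`. Downstream stages
declare the columns they need; the readers never impute.

## Cluster scores

For each missense event, the score counts the *other* events within ±7
residues and divides by the distance to the nearest other event. Three
conventions are not derivable from the score's verbal definition and are
fixed (and configurable) here:

- the index event is excluded from its own window count, so an isolated
  mutation scores 0 (the natural "no clustering" baseline);
- distinct substitutions at the same position count as neighbours, and a
  nearest distance of 0 is clamped to 1 — co-positional recurrence is maximal
  clustering, not a division by zero;
- an event with no neighbour inside the window has ratio 0 regardless of the
  nearest distance.

`prox_ratio_each` uses each protein's own positions; `prox_ratio_all`
projects all members' events onto alignment columns (not reference
numbering, so indels cannot distort distances) and pools them;
`pclust_score` is their exact sum. The window half-width default of 7
residues reflects the first quartile of nearest-neighbour distances among
somatic missense mutations in large cancer catalogs. The vectorized
implementation is checked exactly against an independent O(n²) pure-python
oracle on 1,000 random event multisets.

## Activity normalization and classification

Raw plate signals normalize as (mutant − background)/(WT − background),
floored at 0; a wild-type signal at or below background is an assay failure.
Replicates aggregate to mean and sample SD. The *neutral band* is the mean
± 1 sample SD of activities among variants retaining > 50% of wild type,
per substrate channel (unmodified `me0`, monomethylated `me1`).

Labels partition every variant exactly once, with GOF taking precedence:

- **GOF/gain** — activity above band mean + 2σ on either channel;
- **GOF/switch** — primary-channel activity < 0.5 while the other channel
  exceeds its band (the product-specificity-switch phenotype);
- **LOF** — primary activity strictly < 0.5 (exactly 0.5 is neutral);
- **neutral** — otherwise.

The primary channel defaults to `me0` and the GOF multiplier to 2σ; both are
configurable because the source assay defines the 1σ band visually without
printing a numeric gain cutoff.

## Covariates

The modeling table has 14 covariates per variant: six mutant-minus-wildtype
side-chain deltas (heavy atoms; H-bond donors and acceptors; formal charge at
pH 7; Kyte–Doolittle hydropathy; Zamyatnin volume — scale choices recorded in
the shipped property table `data/aa_properties.tsv`), the BLOSUM62 score,
ingested ΔΔG (kcal/mol) and Mutation-Assessor-style FI/VC/VS scores, and the
three cluster scores. ΔΔG and the phylogenetic scores are *ingested, never
computed*: they come from external predictors whose internals are out of
scope. Deltas are antisymmetric by construction; BLOSUM62 is checked against
independently frozen rows of the published matrix.

Column conservation is 1 − H/Hmax with H the Shannon entropy of the column's
residues (gap as a 21st symbol) and Hmax = log min(n, 21). It is the simplest
defensible stand-in for the (unpublished) score behind the family-vs-clade
comparison, so conclusions drawn from it are qualitative: false-positive
positions of a family-conservation-based predictor show clade ≫ family
conservation, true positives much less so.

## Statistical models

**Spearman screen.** Rank correlation (average ranks for ties) of each
covariate with relative activity; two-sided p via the t-approximation,
validated against exhaustive permutation at n = 8. Constant covariates and
columns with < 5 complete pairs are flagged, not guessed.

**Group tests.** The cluster-score stratification splits variants at
pClustScore 1.5 (ties to "low", a convention the source leaves open) and
compares group mean activities with a two-sided Welch t-test. The
family-vs-clade comparison uses a two-factor ANOVA (Type II sums of squares)
of conservation scores on scope (family/clade) × predictor status (FP/TP).

**Principal-components regression.** Covariates are z-scored; the correlation
matrix is eigendecomposed (deterministic sign: each component's
largest-magnitude loading is positive); the top components reaching ≥ 75%
cumulative variance are retained and activity is regressed on their scores
(adjusted R² reported). Two passes are run: a contribution assessment over
all 14 parameters, and the reported model on the 9 significant phylogenetic +
clustering + physico-chemical parameters. Because the summed cluster score is
an exact linear combination of its two parts, the correlation matrix is
intentionally rank-deficient; trailing zero-variance components are never
selected. Loadings are verified against an independent SVD solver to 1e-8.

**Regression tree.** A conditional-inference-style recursion: at each node,
every candidate covariate is tested for association with activity using a
permutation Spearman statistic (9,999 permutations, one seeded generator for
the whole fit), p-values are Bonferroni-corrected over covariates, and the
node splits only if the best adjusted p ≤ α (default 0.05) — so covariate
selection is significance-gated rather than greedy and is unbiased across
measurement scales. The winning covariate splits at the cutpoint maximizing
between-group sum of squares subject to both children ≥ `min_node`
(default 7 ≈ n/14 for n = 99); the threshold is recorded as the midpoint of
the two bracketing observed values. Terminal nodes predict their training
mean. This follows the spirit of the ctree framework with simpler, fully
specified mechanics; it is not a reimplementation of the R package.

**Cross-validation.** "Quantile categorization" is implemented as
decile-stratified fold assignment on the response (configurable off):
each repeat bins activities into deciles, deals each bin's shuffled members
round-robin into k = 10 folds (90/10 train/test), fits the tree on the
training folds and predicts the held-out fold; 10 repeats draw fresh folds.
Pooled held-out predictions and the true activities are both dichotomized at
activity ≤ 0.5 (LOF positive) to form the confusion matrix; the pooled
accuracy is reported with per-repeat accuracies alongside, since the source
does not say which aggregation its printed figure uses.

**Predictor evaluation.** Direct default-threshold classification against
the experimental labels (GOF and neutral count as not-LOF): FATHMM calls
disease at score ≤ −0.75, PolyPhen-2 damaging at > 0.8 (the 0.2–0.8
"possibly damaging" band is reported separately), OPAI oncogenic at ≥ 0.95.
Variants with missing scores are excluded and counted. Single-score
actual-vs-predicted adjusted R² comes from an ordinary least-squares fit of
activity on the score.

Randomness policy: one top-level seed (default 20221102) governs the
generator, every permutation test and every fold draw; identical
configuration and seed reproduce every serialized artifact byte for byte.
Missing data are handled by listwise deletion per model fit with logged
counts.

## The synthetic study generator

`synthetic.generate` emulates the screen the pipeline was built for:

- a 260-residue construct; a six-member family in three clades of two
  (variants on three members, 29/44/26); member offsets mimic full-length
  numbering;
- sequences evolve ancestor → clade → member with substitution rates
  0.10/0.05; ~10% of columns are clade-specific (conserved within every
  clade, divergent between clades). The alignment is evolved *after* variant
  placement so the columns hosting PolyPhen-2 false positives can be forced
  clade-specific without distorting the spatial placement of neutral
  variants;
- labels are apportioned exactly (61/35/3 of 99) and shuffled; LOF variants
  fall inside one of five 9-residue hotspots with probability 0.8, all other
  variants are uniform. Five hotspots echo the five structural clusters of
  the modeled enzyme family; their 9-residue width is of the order of a
  secondary-structure element and was calibrated, within the stated study
  conditions, so the planted constructions (cluster-score/activity contrast,
  two-parameter CV accuracy ≥ 0.85 across seeds) are actually realized in the
  emitted data;
- activities are truncated normals per label (LOF 0.15 ± 0.10, neutral
  1.00 ± 0.15, GOF 1.8 ± 0.3 on the gained channel) with two simulated
  replicates (noise SD 0.05). Gain-mode GOF keeps neutral-like activity on
  the unmodified-substrate channel — the gain is on `me1` — and switch-mode
  GOF loses `me0` while gaining `me1`;
- predictor scores are drawn conditionally on the planted label: FI
  ~ N(3.5, 0.6) for LOF vs N(1.5, 0.8) otherwise (VC/VS are noisy linear
  functions of FI); FATHMM/PolyPhen-2/OPAI call rates use
  sensitivity/specificity pairs (0.06/0.97, 0.86/0.10, 0.64/0.62) read off
  the quadrant fractions the modeled study prints, with scores drawn
  uniformly inside the called / not-called region.

What the generator does **not** emulate: linkage between physico-chemical
severity and functional label (deltas come from real residue pairs but the
label does not depend on them), indels (off by default, which keeps
ProxRatioAll ≥ ProxRatioEach exact), assay-plate artifacts, and the
confounding structure of real mutation catalogs. Passing tests therefore
demonstrate that the *machinery* recovers planted structure under realistic
noise — not that real variant data will be this clean.

Two small fixtures serve parameter-recovery tests: `planted_step_dataset`
(a step response with an empty gap around the threshold, for split-recovery
checks) and `planted_hierarchy_dataset` (loss of function driven by high
conservation score *or*, among low-conservation variants, by high cluster
score — the two-level structure the pipeline's tree should reproduce).

## Numerical and degenerate-case choices

- Welch (unequal-variance) t-test wherever "unpaired two-tailed t-test" is
  called for; each group needs n ≥ 2.
- Tree cutpoints only between strictly distinct covariate values; ties in
  the between-group criterion break toward the lower threshold; a node with
  no valid cutpoint becomes terminal.
- Permutation p-values use the add-one estimator (1 + #{|T*| ≥ |T|})/(B + 1)
  with B = 9,999, so they are never zero.
- pClustScore stratification sends ties at the threshold to the low group.
- Variant tables reject synonymous rows, nonstandard residues and duplicate
  (protein, position, mutant) keys at parse time, naming the offending row.
- Floats are parsed with round-trip precision so write → read → write is
  byte-stable.

## Known limitations

- The cluster-score stratification at the fixed 1.5 threshold is a moderate
  effect (t ≈ 3) under the study-scale density of 99 events on 260 columns:
  at the default configuration it is highly significant (Welch p ≈ 4e-5),
  but across re-seeded replicates of the generator the p-value fluctuates and
  can exceed 0.01 — a sampling-variability property of the study design
  itself, not of the implementation.
- The per-program accuracies depend on the LOF base rate; with 62% LOF a
  predictor calling almost nothing (FATHMM-like) cannot exceed ~40%
  accuracy, so simulated accuracies track the modeled study's quadrant
  fractions rather than its printed accuracy table, which is not internally
  consistent with its own base rate.
- The conservation metric is a stand-in (see above); family-vs-clade results
  are qualitative.
- Problem sizes throughout (99 variants, 10×10-fold CV, 9,999 permutations,
  1,000-set oracle sweeps) are the package's defaults and run in seconds on
  one CPU.
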