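# Methods

`splicespan` implements a comparative analysis linking alternative-splicing
(AS) inclusion levels to species maximum lifespan (MLS), body mass (BM) and
human age. Because the real datasets behind such an analysis (multi-species
RNA-seq, a GTEx-scale human cohort) cannot ship with a package, every stage
is exercised on synthetic data with planted effects and known ground truth;
this note records the models, the defaults, and what the synthetic results
do and do not establish.

## Events and PSI

Seven AS event types (SE cassette exon, A5/A3 alternative splice sites, MX
mutually exclusive exons, RI retained intron, AF/AL alternative first/last
exons) are extracted from transcript exon chains by pairwise junction
comparison, in the transcript-centric style of SUPPA. Inclusion/exclusion
transcript sets are recomputed over all of a gene's transcripts, so events
are independent of the pair that first revealed them. A5/A3 assignment is
strand-aware (5′/3′ are defined on the mRNA, not the genome). Event ids are
canonical strings `type:gene:chrom:coords:strand`, making runs comparable.

PSI of an event in a sample is `100 · ΣTPM(inclusion) / ΣTPM(inclusion ∪
exclusion)`, undefined (NA, never 0) when the denominator is zero. PSI is
kept on the 0–100 scale throughout; the range filter (≥ 20) only makes sense
in percent units. Species-level PSI is the unweighted mean over that
species' samples in a tissue. Event filters: gene TPM > 0.5 in at least
⌈n/3⌉ samples (rounded up — conservative and deterministic), PSI range over
non-missing values ≥ 20, and non-missing PSI in ≥ 10 species.

## Homology mapping

Events are matched across species by local alignment of their defining
regions against the anchor species (the best-annotated genome, playing the
role mouse plays for real data). Scoring is BLAST-like: match +1, mismatch
−2, gap open −2, gap extend −1 (Biopython's `PairwiseAligner`, local mode).
A call is accepted when every required region covers ≥ 80% of the *anchor*
region length in the best local alignment — anchor-based coverage is the
reproducible choice given the anchored design; for two-exon types (MX, AF,
AL) both alternative exons must qualify. Among qualifying candidates the
highest mean coverage wins; ties break by smaller genomic span, then
lexicographic event id. Events accepted in ≥ 10 species form the conserved
set. Only the alternative region(s) participate by default; flanking
constitutive exons can be added through the per-type region-role map in
configuration.

## MLS association

Per event and tissue, Spearman's rank correlation between species PSI and
the trait (MLS or BM, both untransformed by default; a log option exists),
on pairwise-complete species, p-values by the t-approximation (adequate at
n ≥ 10; exact permutation is available behind a flag). BH-FDR is applied
per tissue × trait family. Significance: |ρ| > 0.4 and FDR < 0.05.

Phylogenetic correction uses Felsenstein's independent contrasts: at each
internal node of the (resolved) tree, `(x_L − x_R)/√(b_L + b_R)` with the
ancestral branch lengthened by `b_L·b_R/(b_L+b_R)`. The corrected
correlation is the through-origin Pearson correlation of the PSI and trait
contrasts (the standard choice, since contrast signs are arbitrary); an
association is *retained* when |r| > 0.2 and the sign matches the raw ρ.
One caveat the tests document: when both variables are strongly clade-
structured, the single deep-split contrast dominates the through-origin
correlation, so contrast correlation discounts clade-driven signal only
when the between-clade shift is modest relative to within-clade,
branch-standardized variation.

The BM decomposition fits `MLS = β₀ + β₁·BM + β₂·PSI` by OLS on complete
triples and classifies events by the coefficient t-tests: PSI_only
(p₂ < 0.05, p₁ > 0.05), joint (both), BM_only, neither.

Tissue specificity: an event is brain-divergent when it is significant in
the focal tissue (default "brain", a parameter) with a ρ sign opposite to
its sign in every other tissue where ρ is defined; with no opposing
evidence the flag stays off.

## Age association

Age is regressed on all events simultaneously: elastic net (mixing 0.5)
over the standardized PSI block plus *unpenalized* covariates (sex, five
genotype PCs, fifteen expression-factor surrogates, platform, protocol —
they are adjustments, not candidates). Unpenalized covariates are handled
exactly by Frisch–Waugh partialling-out: age and the PSI block are
residualized on the covariate design, and the penalized model is fit on the
residuals; profiling the covariate coefficients out of the joint objective
shows this is the identical optimum. Events with any missing PSI are
dropped (the model needs a complete matrix); one-hot encoding is
lexicographic for determinism.

The penalty is chosen by seeded 10-fold cross-validation with the
one-standard-error rule on a 30-point path bounded below at 1% of the
maximal penalty (`eps = 0.01`): the sparsest model whose CV error is within
one SE of the minimum, the `lambda.1se` convention of glmnet. This rule is
what makes the permutation null sharp — under a label permutation the
1-SE model collapses to (near-)empty, whereas the CV-minimum rule
occasionally picks a tiny penalty on permuted labels and floods the null
with spurious selections, and reusing the signal-tuned observed penalty
under permutation inflates null selections past the observed count
(empirical FDR > 1). Empirical FDR therefore reruns the *entire*
procedure — residualization, CV, 1-SE — on each of 500 age-shuffled copies
and reports mean permuted selections / observed selections above each
absolute standardized-coefficient cutoff (cutoffs are on the standardized
scale). On a null cohort the observed count is exchangeable with the
permuted counts by construction.

Set similarity uses Jaccard and the overlap coefficient. The MLS ∩ age
overlap test draws |A| and |B| identifiers from their respective
backgrounds 10,000 times, counts overlap on the shared identifier space,
and reports add-one empirical p-values for depletion and enrichment; with a
common background it converges to the exact hypergeometric tails (tested).

## Overlap statistics

Hypergeometric tails and the conditional Fisher exact test (which coincide
one-sidedly — both entry points are provided), BH-FDR by the step-up rule,
a local gene-set enrichment over GMT collections on a user-supplied
background (one-sided, FDR-thresholded at 0.15 by default), and an
interval-overlap test (an event overlaps an IDP region when any defining
interval shares ≥ 1 nt, half-open arithmetic) reduced to a 2×2 Fisher test
against background events.

## RBP motifs

Scan regions concatenate an event's exonic/intronic sequence with flanks
(exon ± 100 nt, intron ± 50 nt), strand-resolved upstream so scanning is on
the sense strand only. IUPAC consensus motifs count all (overlapping) match
start positions; N in the sequence never matches. PWMs count positions
scoring above a threshold expressed as a fraction of the attainable score
range. Rates are counts per scanned nucleotide, flanks included.

Group enrichment draws 500 random event groups matched exactly on the
target's AS-type composition (without replacement) and reports target mean
rate divided by the mean of per-draw mean rates. Because draws come from
the full universe, a target that is a fraction `f` of the universe with a
planted `m`-fold rate sees its ratio diluted to `m / (1 + (m−1)f)`; the
recovery tests keep `f` small so this bias stays inside their tolerance.
Per-event motif load is summarized as within-RBP percentile ranks (average
ranks for ties, scaled to [0, 100]) and biclustered by average-linkage
hierarchical clustering on Euclidean distance with identifier-sorted,
deterministic leaf order. Cross-species motif-frequency/PSI association
reuses the Spearman machinery and requires strictly more than 10 paired
species. A paired t-test over shared top-ranked RBPs compares two groups'
enrichment profiles.

## Intervention

Condition-level PSI comes from median-across-replicates inclusion/exclusion
read counts; the per-event test for an inclusion increase is a one-sided
Fisher test on the 2×2 count table with BH-FDR across events. Events are
labeled pos-MLS / neg-MLS / background from the cross-species results, and
the fraction significantly upregulated (ΔPSI > threshold and FDR < 0.05) is
compared between each MLS category and background over the threshold grid
{0, 5, 10, 15} (pos-MLS tested one-sided "greater", neg-MLS "less").

## Synthetic study conditions

The generator fixes the conditions every recovery test runs under:

* **Tree and traits.** A pure-birth tree with 26 tips (birth rate 1);
  tip edges are extended by one exponential waiting time because the
  simulator stops exactly at the last speciation (which would leave
  zero-length branches), and the simulator's pre-root origin branch is
  dropped. log MLS and log BM evolve by correlated Brownian motion
  (rate 0.5, correlation 0.5) and are monotonically rescaled to 2.2–37
  years (>16-fold) and a 2000-fold mass range; the realized MLS–BM rank
  correlation varies around the Brownian parameter across seeds.
* **Species PSI.** Planted events (10% of 500 per tissue): logit(PSI/100) =
  a + b·z(log MLS) + Brownian noise + iid noise with |b| = 1, giving a true
  |ρ| ≈ 0.7. Noise is split into a phylogenetic part (tip SD 0.15, Brownian
  on the same tree) and an iid part (SD 0.92); the split was calibrated so
  null events—whose phylogenetic noise shares the tree with MLS—keep the
  false-positive rate of the significance rule at or below its nominal
  level while preserving genuine signal-vs-phylogeny structure for the
  contrast stage. A fifth of planted events flip their effect sign in the
  focal tissue (the brain-divergent subset). Missingness 5% per
  species×event. Logit-scale generation with clipping avoids boundary
  pile-ups that would distort ranks.
* **Sequences.** Anchor regions are uniform ACGT (200 nt); orthologs mutate
  per site at `divergence_rate × patristic distance to the anchor tip`
  (capped at 0.75), and 10% of species lose an event outright.
* **Cohort.** 400 samples, ages uniform 20–70; 20 of 500 events carry
  0.5 PSI/year slopes (≈ 25 PSI units across the age range) against 7 PSI
  units of residual noise — strong-but-plausible effects sized so planted
  events separate from the permutation null; 10 confounded events instead
  track a covariate that itself correlates with age (loading 0.6), which a
  correctly adjusted model must reject. All events load mildly on two
  genotype PCs.
* **Motif regions.** Random background sequence with enriched RBPs' motifs
  stamped at non-overlapping positions (base 0.02/nt, ×3 in planted
  events); non-stamped RBPs occur at their consensus' background frequency,
  so their enrichment ratio is ~1 by construction.
* **Intervention.** Control PSI uniform 20–80; treatment shifts pos-MLS
  events +15 and neg-MLS events −15 PSI; binomial counts at depth 500.

What passing these tests shows: the estimators recover effects of the
stated size under the stated noise, error control is calibrated under the
generator's null, and boundary rules (80% coverage, 10 species, range 20,
>10 points) behave exactly as specified. What they do not show: robustness
to real-data pathologies the generator omits — isoform-quantification
error correlated across events, non-uniform missingness, assembly artifacts
in de novo transcriptomes, batch structure beyond linear covariates, and
realistic sequence evolution (indels, splice-site turnover).

## Numerical choices and limitations

Problem sizes in the test-suite and acceptance runs (500 events × 6 tissues
× 26 species; 400 × 500 cohort with 500 permutations; 500 resampling draws;
1500-event motif universes) were chosen so a complete run finishes in
minutes on one CPU while keeping Monte-Carlo error well inside every
asserted tolerance. Alignment-coverage equality with the brute-force
dynamic-programming oracle is asserted on optimal *scores*; co-optimal
alignments can differ in coverage, so coverage itself is asserted only on
constructs where the optimum is unique. Degenerate inputs follow explicit
rules: zero PSI denominators are missing, constant vectors are dropped from
correlation testing, empty categories report missing fractions, odds ratios
with zero denominators are infinite, and permutation p-values use the
add-one convention. The pipeline is a sequence of plain-TSV stages with the
seed and a configuration hash in every header; a rerun at the same seed is
byte-identical.
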