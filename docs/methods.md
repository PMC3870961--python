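# Methods

## The genetic design

The package analyzes a five-line autosome-substitution panel of the house fly
(*Musca domestica*). The resistant parental strain (ALHF) carries resistant
"R" alleles on all five autosomes; the susceptible marker strain (aabys)
carries susceptible "S" alleles, each tagged by a recessive morphological
marker. Each substitution line A2345 … A1234 is ALHF-like except for exactly
one autosome replaced by its aabys counterpart; the name lists the autosomes
retained from ALHF, so A1234 substitutes autosome 5. Lines are modeled as
homozygous at every retained R autosome — the permethrin selection used to
construct such lines fixes them — so heterozygote and dominance effects are
outside the model.

The analytical idea: if substituting autosome *a* significantly changes a
gene's expression relative to ALHF, autosome *a* carries at least one
regulatory factor for that gene. The set of such autosomes is the gene's
*linkage set*. Partitioning genes by their exact linkage subset (the Venn
partition) reveals co-regulation classes; combining the linkage set with the
gene's physical autosome (from allele-specific PCR) classifies regulation as
cis (regulatory autosome = the gene's own), trans, or both.

## Expression model of the simulator

Ground truth per gene is a physical autosome, a subset of "factor"
autosomes, and a positive log2 effect `beta_a` per factor. Expected log2
expression in a genotype *g* is

    log2 E = baseline + sum_{a in factors, g[a] = R} beta_a

i.e. additive on the log2 scale, multiplicative in linear scale. The
substitution design cannot distinguish additive from all-or-nothing
epistasis; additive is the default because the published panel shows
*partial* loss of up-regulation under single substitutions. An `and` mode
(full effect only when every factor autosome is R) is available behind the
scenario's `model` key for sensitivity analyses.

Assays are emulated as:

* **Replicate expression** — linear value `2^(expected + eps)`,
  `eps ~ N(0, noise_sd^2)` independent per replicate (lognormal measurement
  noise).
* **Sequencing counts** — a sample's library depth apportioned over genes by
  expression x length, drawn NB with dispersion `phi`
  (variance `mu + phi*mu^2`; `phi = 0` is Poisson). Expected FPKM is thereby
  proportional to linear expression. Library size is recorded explicitly as
  the FPKM denominator.
* **Ct values** — `Ct = intercept − log2 E + eps`, with a strain-constant
  reference gene (the panel's beta-actin control behaved as constant), and
  perfect doubling efficiency as assumed by the 2^-ddCt formula. The
  generator is the exact inverse of the quantification stage: with zero
  noise, 2^-ddCt recovers the simulated fold-changes to machine precision.
* **AS-PCR bands** — present exactly where the line carries the R allele of
  the gene's physical autosome; deterministic by default (a `dropout_rate`
  flag exists for robustness checks, default 0).

Defaults: 200 genes, triplicates, `noise_sd = 0.15` log2 units (qPCR
replicate scatter is not published for the panel; 0.15 cycles is a typical
well-run SYBR assay), per-factor effects uniform on [0.8, 1.6] log2
(2-3 fold per factor, matching the panel's printed fold-changes),
`phi = 0.05`, depth 1e5 fragments. Factor-subset class priors default to the
frequencies of the 59-gene published partition (21/59 on {2,5}, 9/59 on
{1,2,5}, …), so a default simulation reproduces the study's architecture
mix. Regulated genes sit on one of their own factor autosomes with
probability `p_cis = 0.8` (all eight published mapped genes did; 0.8 leaves
room for trans-only architectures, which are known from other resistance
loci).

What the generator does **not** emulate: read-level sequence data, assembly
or annotation error, primer efficiency differences, within-autosome
recombination or linkage disequilibrium, and between-biological-replicate
effects beyond lognormal noise. Passing recovery tests therefore validate
the inference logic under the design's idealized assumptions, not the wet-lab
steps.

## Quantification and significance calling

2^-ddCt with a single endogenous reference: per sample,
`dCt = mean Ct(target) − mean Ct(reference)`, `ddCt` subtracts the
calibrator's dCt, relative expression is `2^-ddCt` (calibrator exactly 1
regardless of noise). Replicate-level values pair each target replicate with
its same-index reference replicate so that reference noise appears in the
within-sample spread; normalizing all replicates by the mean reference Ct
would hide that variance from the standard error and bias the t-tests
liberal. Efficiency correction (Pfaffl), standard curves and multi-reference
normalization are out of scope.

Each line is compared to ALHF with a two-sided Welch test on the
linear-scale replicate values (matching how the published panel was tested):
`t = (m1 − m2)/sqrt(se1^2 + se2^2)` with Welch–Satterthwaite df. With both
SEs zero the test degenerates: p = 1 for equal means, p = 0 (flagged) for
different means — this is what makes noiseless end-to-end recovery exact. No
multiple-testing correction is applied across lines or genes at this stage,
matching the per-test alpha = 0.05 design; the BH correction lives only in
the sequencing screen. Measured on null simulations (no factors, n = 3,
alpha = 0.05) the flag rate is ≈ 0.03–0.04, slightly conservative, as
expected for Welch at tiny n.

When only printed summaries exist (the packaged panel), the
summary-statistic Welch formula applies, but the published asterisks are
treated as the authoritative calls: printed SEs are rounded to 1–2 digits,
so p-values recomputed from them (`welch_diagnostics`) are diagnostic only
and never override the flags.

## Linkage sets, the Venn partition, and cis/trans

Autosome *a* joins a gene's linkage set iff the line substituting *a* is
flagged significant versus ALHF — in either direction: four protease genes
in the published panel are significant in A1235 with mixed directions, and
the exact-subset partition places them in their published classes {3,4,5}
and {2,4,5} only if both directions count. Autosome 4 participates fully in
the partition. Genes whose rows carry no usable data are status `no_data`
and excluded from the partition denominator (59 of the 70 panel genes
remain).

AS-PCR mapping: exactly one bandless substitution line → mapped to that
line's substituted autosome; no bandless line → unmapped; two or more →
ambiguous; a parental inconsistency (no ALHF band, or an aabys band) →
ambiguous with a note. Replicated patterns merge by majority vote, ties →
ambiguous. Band intensity is not modeled.

Classification: `cis_only` (linkage = {location}), `trans_only` (location
not in a non-empty linkage set), `cis_plus_trans` (location plus others),
`unlinked` (empty set). "Cis" is autosome-level coincidence only — the
design cannot distinguish a cis regulatory factor from the gene's own
structural locus, so cis_plus_trans calls carry a `cis-or-locus` flag.

## The sequencing screen

A deliberately desk-scale stand-in for a full RNA-seq DE analysis:

* **FPKM** = `1e9 * count / (length_nt * library_size)`.
* **Library equalization** — total-count scaling to the geometric-mean
  depth. TMM/RLE are not implemented; compositional shifts between groups
  are therefore not corrected, and the screen's error benchmark holds
  per-gene sequencing effort fixed so that it scores the test rather than
  the normalizer.
* **Common dispersion** — method of moments: per gene,
  `max(0, (s^2 − m)/m^2)` from the pooled within-group variance and overall
  mean of equalized counts; the estimate is the median over genes. With only
  a few samples the pooled variance has very few degrees of freedom and its
  *median* across genes sits near `chi2_median(d)/d` of the truth, so the
  raw median-of-moments estimate is biased low — low enough to visibly
  inflate the downstream false-discovery rate. The pooled variance is
  therefore rescaled by `d / chi2_median(d)`, which makes the median over
  genes consistent; at n = 2 per group and true phi = 0.05 the estimate
  lands at ≈ 0.05 instead of ≈ 0.024.
* **Exact test** — conditional on each gene's total equalized count: outcome
  weights are the product of the two group-sum NB pmfs under the null common
  mean (group sums of n NB(mu, phi) samples are NB(n*mu, phi/n)); the
  two-sided p-value accumulates all splits with probability at most the
  observed one, ties included (conservative). phi = 0 reduces exactly to the
  conditional binomial test.
* **BH step-up** at FDR 0.05 (statsmodels), then the intersection of the
  two comparisons defines co-up-/co-down-regulated sets; direction
  conflicts belong to neither.

Measured at the reference conditions (2000 genes, 10% truly up at log2FC 2,
depth 1e5, phi 0.05, n = 2 per group), the screen's empirical FDR is
≈ 0.02–0.06 and power ≈ 0.84–0.92 across seeds. Tagwise dispersion
shrinkage, GLM designs and exon-level quantification are out of scope, and no
attempt is made to match any specific published gene list obtained with
different software on raw reads.

## Numerical and design notes

* All generators take integer seeds (numpy `default_rng`) and are bitwise
  reproducible.
* The exact test's enumeration is O(total count) per gene, vectorized; at
  the benchmark depth this is milliseconds per gene.
* `nb_exact_test` compares probabilities with a relative tolerance of 1e-12
  when collecting the tail, so ties are included deterministically.
* Welch significance on the Ct pathway is computed on linear-scale relative
  expression, not log-scale, to match the panel's published analysis.
* Problem sizes in the test-suite experiments (100–2000 genes, 300-gene
  band panels, 5500 null line tests) were chosen as the smallest sizes at
  which the binomial/Monte-Carlo error of each measured rate is comfortably
  inside the asserted band.
* The Venn partition is stored as an exact mapping subset → genes; no
  graphical Venn rendering is provided (a five-set Venn is not readable and
  the counts table carries the same information).

## Known limitations

* Autosome-level resolution only: no within-autosome mapping, no candidate
  factor identification.
* The panel fixture's significance calls inherit whatever test the original
  analysis used; the package reproduces the published partition from the
  printed flags rather than re-deriving it from raw replicates, which are
  not public.
* The linkage caller treats the five line tests per gene as independent at
  alpha = 0.05; with ~3 null lines per gene this yields a ~10% chance of at
  least one spurious edge per gene, visible as the ~90–94% (not 100%)
  stochastic exact-set recovery.
* The DE screen's single common dispersion underfits genes with atypical
  biological variability; it is a screen, not a final analysis.
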