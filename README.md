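# flylinkage

Autosome-level linkage analysis of gene co-regulation in an
autosome-substitution panel of the house fly (*Musca domestica*).

Insecticide-resistant house flies up-regulate whole batteries of
detoxification and signaling genes, and the regulatory factors behind that
up-regulation sit on specific autosomes. Given a resistant parental strain
(ALHF, all-resistant autosomes), a susceptible marker strain (aabys), and
five lines each substituting exactly one ALHF autosome with its aabys
counterpart (A2345 … A1234, the name listing the autosomes kept from ALHF),
one can ask, gene by gene: *which autosome substitutions significantly change
expression?* Those autosomes carry regulatory factors for the gene — its
**linkage set**. This package implements that inference end to end, for
researchers working with chromosome/autosome-substitution designs:

* **2^-ddCt qPCR quantification** with reference-gene normalization and
  per-line Welch t-tests against the parent
  (`ddct`, `summarize_lines`);
* **linkage-set calling and Venn partitioning** of genes into exact
  co-regulation classes such as {2,5} = "needs factors on both autosomes 2
  and 5" (`call_linkage`, `venn_partition`);
* **allele-specific-PCR physical mapping** — the one substitution line
  lacking the ALHF-allele band localizes the gene (`infer_location`);
* **cis/trans classification** by intersecting linkage sets with physical
  locations (`classify`);
* a **negative-binomial differential-expression screen** (FPKM, conditional
  exact NB test, Benjamini–Hochberg FDR, two-comparison intersection) for
  nominating co-up-regulated genes from counts (`de_test`,
  `co_regulated_sets`);
* a **synthetic-data generator** that emulates the whole genetic design with
  known ground truth — expression, counts, Ct values and band patterns — so
  every stage is testable without any external data (`Scenario`,
  `sample_architectures`, `simulate_*`).

The statistical core in one line: for gene *i* with factor-autosome set
*F_i* and effects *β_a > 0*, expected log2 expression in genotype *g* is
`baseline_i + Σ_{a ∈ F_i, g[a]=R} β_a`; replacing any factor autosome drops
expression by β_a log2 units, and the Welch flag pattern across the five
lines recovers *F_i*.

A transcription of the published 70-gene qPCR validation panel ships as a
fixture (`flylinkage/data/table4_expression.tsv`), along with a synthetic
reconstruction of the published eight-gene AS-PCR mapping, so the package
reproduces the study's co-regulation partition out of the box.

## Worked example

```python
from flylinkage import (
    load_table4, call_linkage, venn_partition,
    subset_count, single_autosome_summary,
)

summary = load_table4()                 # the packaged 70-gene panel
calls = call_linkage(summary)           # printed flags -> linkage sets
partition = venn_partition(calls)

print(partition.n_called)               # 59  (genes with usable data)
print(subset_count(partition, {2, 5}))  # 21  genes co-regulated by 2 and 5
print(subset_count(partition, {1, 2, 5}))  # 9
print(subset_count(partition, {2, 3, 5}))  # 6
print(single_autosome_summary(partition))
# ({1: 0, 2: 4, 3: 1, 4: 0, 5: 6}, 11)
```

Of the 59 analyzable genes, 21 need factors on both autosomes 2 and 5, nine
on 1+2+5, six on 2+3+5, and only 11 depend on a single autosome (none solely
on 1 or 4) — multi-autosome co-regulation dominates. Combining linkage with
the AS-PCR locations:

```python
from flylinkage import run_fixture_report
report = run_fixture_report()
print({c.gene_id: c.reg_class for c in report.classes})
```

classifies the eight physically mapped genes: one P450 is `cis_only`
(regulated solely from the autosome it sits on); the other seven are
`cis_plus_trans`.

The `examples/` directory holds one short narrative script per capability
(simulation, qPCR quantification, linkage/Venn, AS-PCR mapping, cis/trans
report, DE screen, recovery experiment); each prints the numbers it computes
and a line on what they mean. A thin CLI mirrors the stages:
`flylinkage simulate|quant|de|tally|linkage|map|report --help`.

## Scope

Autosome-level inference only: no within-autosome mapping, no primer or
sequence-level analysis, no transcriptome assembly or annotation. See
`docs/methods.md` for the model, its assumptions, parameter defaults and
limitations.
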