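# braincirc

Cell-type-resolved analysis of circular RNAs (circRNAs) from back-splice
junction (BSJ) read counts, built for laser-capture RNA-seq designs that
profile dopamine neurons (DA), pyramidal neurons (PY) and non-neuronal cells
(NN) from post-mortem human brain. The package takes the output of an
upstream chimeric-read circRNA caller (BED12+ records plus count matrices)
and carries it through validation filtering, cell-type specificity scoring,
host-locus architecture, genomic feature characterization, gene-set and
disease enrichment, and case/control differential expression. A seeded
synthetic-data generator reproduces the statistical structure of such a study
so that every stage is testable without access to protected human data.

## The methods at its core

**RNase-R validation filter.** RNase R is a 3'→5' exoribonuclease that
digests linear RNAs but spares covalently closed circles. A candidate circRNA
with at least 2 unique BSJ reads overall is *validated* when, in at least one
paired treated/mock experiment, it has ≥ 20 raw reads in the treated library
and ≥ 2-fold enrichment of library-size-scaled (per-million) counts over the
mock library.

**Jensen-Shannon specificity score.** For circRNA *c* with mean RPM profile
across cell groups expressed as the density *p_c* of (RPM + 1), and the
one-hot "perfect expression" profile *q̂_i* of group *i*,

    S_{c,i} = 1 − JSD(p_c, q̂_i),

where JSD is the Jensen-Shannon distance (square root of the base-2
Jensen-Shannon divergence), so S ∈ [0, 1]. A circRNA is *cell-type specific*
when S ≥ 0.5 and its group mean exceeds the across-sample mean plus one
standard deviation of its own expression. Loci whose specific circles all
belong to one group are *exclusive* producers; loci tailoring distinct
specific isoforms to ≥ 2 groups are *super-hosts*.

**Enrichment.** Host genes of specific circRNAs are tested per gene set (or
disease, from a gene–disease association table filtered at GDA score > 0.1)
with the one-sided Fisher/hypergeometric upper tail on (k, K, n, N),
Benjamini–Hochberg FDR, and greedy Jaccard slimming of redundant terms.

**Differential expression.** CircRNA counts are aggregated per host gene and
fit with a negative-binomial GLM (log link, median-of-ratios size factors as
offsets, covariates sex, age, PMI, RIN). Per-gene dispersion is estimated by
Cox–Reid-adjusted profile maximum likelihood; the condition effect is tested
with a Wald statistic referred to a t distribution with n − p degrees of
freedom.

## Worked example

Generate a synthetic study under the default conditions and run the stages
(the numbered drivers under `analysis/` do exactly this):

```sh
python analysis/01_simulate.py
python analysis/02_filter_validation.py
python analysis/03_specificity.py
python analysis/04_locus_architecture.py
```

which prints, among other lines:

```
genes: 500, candidate circRNAs: 2033 (243 ciRNA)
true circles: 1634 (399 designed linear artifacts)
...
validated: 1634 (80.4%)
true-circle sensitivity: 100.0%  artifact pass rate: 0.0%
...
specific circRNAs called: 727 (designed: 745, recovered: 727, 97.6%)
per group: {'DA': 244, 'NN': 237, 'PY': 246}
circ vs linear specificity: median dS = 0.025, signed-rank p = 3.42e-306
...
locus architecture: {'super-host': 160, 'none': 110, 'exclusive-DA': 66,
                     'exclusive-PY': 62, 'exclusive-NN': 61}
circular-to-linear ratio medians: neuron 1.52 vs non-neuron 0.51
```

Reading these numbers: the validation filter kept exactly the 1,634 designed
true circles and rejected every designed linear artifact; the specificity
stage recovered 97.6% of the circles that were simulated with a 20-fold
expression excess in one cell group, with none called in the wrong group; and
the designed neuron-elevated circular-to-linear ratio shift (three-fold) is
detected by the Mann-Whitney comparison. The same pipeline is available as a
CLI (`braincirc simulate|filter|specificity|loci|features|enrich|diffexp|run`)
driven by a YAML config.

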