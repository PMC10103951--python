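# Methods

## Scope and data model

The package analyses circRNA back-splice-junction (BSJ) calls downstream of
an external chimeric-read caller. All genomic intervals are 0-based
half-open (BED-native); GTF exons are converted on read (`[s, e]` 1-based
closed → `[s−1, e)`). A `CircRecord` carries the circle's interval, strand,
exon blocks (a contiguous run of host-gene exons for exon-derived circles; a
single intron-spanning block for circular intronic RNAs, ciRNAs), host gene
and total BSJ read support. Cell types map onto three analysis groups —
dopamine neurons (DA), pyramidal neurons (TCPY/MCPY → PY) and non-neuronal
cells (PBMC/FB → NN) — through a configurable table; a 5-cell-type mode is
available for specificity scoring.

## Validation filtering

Expression support requires ≥ 2 unique BSJ reads summed over all samples.
RNase-R validation requires, within at least one treated/mock pair, ≥ 20
reads in the treated library **on the raw count scale** and ≥ 2-fold
enrichment **on the per-million scale**. The split is deliberate: the read
floor is a literal unique-read requirement, while treated and mock libraries
differ in depth, so a raw-count fold would conflate depth with enrichment.
Both criteria must hold within the same pair. A circle with treated reads
and a fully digested mock (zero counts) receives fold +∞ and passes the fold
test — complete digestion of the linear background is the expected behaviour
for a true circle; zero treated reads give fold 0. Both thresholds are
configurable; raising either can only shrink the validated set, which the
tests verify against brute-force re-evaluation.

## Specificity score

S = 1 − JSD(p, q̂) with the Jensen-Shannon distance taken base-2 and as the
square root of the divergence, so S ∈ [0, 1] and S = 0.5 is attainable;
p is the density of (mean RPM + 1) across groups and q̂ the one-hot profile.
Because q̂ is one-hot the divergence collapses to a closed form in the single
density entry p_t at the target group; the tests verify this closed form
against a generic numeric Jensen-Shannon oracle to 1e-12. The (+1) offset
makes the density strictly positive, so all-zero circles score the uniform
value (≈ 0.322 for three groups) and are never called specific.

Classification: specific iff S ≥ 0.5 **and** the group mean RPM exceeds the
across-sample mean plus one sample standard deviation (n−1 denominator) of
that circle's RPM over all included samples. "Overall expression" is read as
the per-circle across-sample distribution — the only reading in which the
standard deviation does meaningful work. Only control-condition samples
enter, so disease-driven shifts cannot masquerade as cell-type identity. A
circle is assigned to at most one group: the highest-S group among those
passing both criteria, ties broken in fixed order (DA, PY, NN).

## Locus architecture and circular-to-linear ratios

A locus is `exclusive-X` when all its specific circles belong to group X and
`super-host` when they span ≥ 2 groups. The circular-to-linear ratio is
circ_reads / (mean(donor_linear, acceptor_linear) + 1): linear abundance at
the back-splice site is summarized as the arithmetic mean of the
donor-spanning and acceptor-spanning linear junction reads (the source
protocol says only "surrounding the back-splicing site"; the mean of both is
the symmetric choice), and the pseudocount of 1 read bounds the ratio when
the linear cognate is absent. Ratios are computed from counts summed over a
sample group. Group comparisons use a two-sided Mann-Whitney U: exhaustive
enumeration of labelings (with midranks under ties) for up to 16 pooled
observations, the tie-corrected normal approximation above that.

## Genomic features

Flanking introns are taken from the transcript whose exon chain contains the
circle's blocks as a contiguous run; ambiguity is resolved by the longest
transcript. Strict mode rejects circles whose boundaries are not annotated
exon borders; lenient mode falls back to the nearest clean exon gaps and
reports no intron when a boundary falls inside an exon. Upstream/downstream
labels are strand-aware. Overlap counting uses half-open semantics (a peak
touching end-to-start does not overlap) on interval trees. The
non-circularized-exon background is the annotated exons of circRNA-producing
genes not included in any circle block. SNP proximity is measured from the
SNP position to the nearest covered base of a circle interval (0 inside),
with a 1 Mb default window.

## Enrichment

One-sided over-representation per set: p = P(X ≥ k) for hypergeometric X
with universe N, set K, query n; odds ratio from the 2×2 table. The universe
is all annotated genes for gene-set mode and protein-coding genes for
disease mode. Disease tables are filtered at GDA score strictly > 0.1, and
the brain-only mode keeps MeSH classes C10 (nervous system) and F03 (mental
disorders). BH FDR is applied across sets (within each cell group for
diseases). Term slimming is greedy: keep the most significant row, drop any
later row whose member-gene Jaccard similarity with a kept row exceeds 0.7
(threshold configurable; the reference procedure names no parameters, so the
slimmed term count should not be over-interpreted). Ties in p are broken by
set id for determinism.

## Differential expression

CircRNA counts are summed per host gene; size factors are median-of-ratios
over genes expressed in every sample. Each gene is fit with an NB GLM (log
link, log size factors as offsets) on condition plus sex (indicator) and
standardized age, PMI and RIN. Dispersion α (variance μ + αμ²) is estimated
per gene by profile maximum likelihood with a Cox–Reid adjustment
(−½ log det XᵀWX, W = μ/(1+αμ)) on a bounded log-scale search
(α ∈ [1e−8, 10]), iterated once with the refit means, with a
method-of-moments fallback; no shrinkage across genes is applied, so
calibration is established by simulation rather than by matching another
tool's output (a reference NB-GLM implementation serves as a cross-check in
the tests, not as the implementation). The Wald statistic LFC/SE is referred
to a t distribution with n − p degrees of freedom: at the design sizes this
package targets (tens of samples, six design columns) the asymptotic normal
reference is measurably anti-conservative (type-I ≈ 0.06 at nominal 0.05
even with the true dispersion), while the t reference restores nominal
behaviour and converges to the normal for large n. All-zero genes yield
flagged NA rows; IRLS runs to a 1e-8 relative tolerance or 100 iterations
with non-converged genes flagged, not dropped.

A known property of median-of-ratios normalization is composition
sensitivity: when a noticeable fraction of genes moves in one direction, the
per-sample medians absorb part of the shift (with 10% of genes at 2-fold in
one condition, roughly a 7% factor shift at the default design), biasing
null genes slightly and inflating their rejection rate. `nb_wald` therefore
accepts externally supplied size factors (e.g. unit factors for
depth-matched libraries, or factors estimated from control genes); the
estimator-level calibration checks use unit factors on depth-matched
simulations, while end-to-end tests run the default path and tolerate the
correspondingly wider effect-size band.

## Synthetic data

The generator emulates the study design stage by stage, each with a child
generator derived deterministically from the master seed (so outputs are
bitwise reproducible per stage and end to end).

* **Annotation.** 500 genes by default, 2–20 exons (uniform), exon lengths
  80–400 bp, intron gaps 0.2–5 kb, one transcript per gene. Exonic circle
  counts per gene are Poisson with rate proportional to the exon count
  (clipped to 0–8), so the circles-per-gene vs exon-count correlation holds
  by construction; each circle is a contiguous exon run. ciRNA candidates
  arise per intron with probability 0.05. A fraction `frac_artifact` = 0.2
  of candidates is labelled a linear artifact in the truth table.
* **Counts.** BSJ counts are negative binomial with common dispersion
  α = 0.1 (the NB matches the count-model framework used downstream; the
  real data's dispersion is unknown, so the default is chosen for
  testability, not fidelity). The baseline mean is 20 reads at a reference
  depth of 10 M, scaled by each library's size (uniform 5–20 M). A designed
  15% of true circles per group get a 20-fold mean excess in their group.
  The control design is DA:20, PY:20, NN:7 samples (NN alternating PBMC and
  fibroblast donors). Linear junction counts (donor and acceptor) are drawn
  independently with neuron libraries' linear means shrunk three-fold,
  producing the designed neuron-elevated circular-to-linear ratio; FPKM
  profiles are flat across groups so linear transcripts carry no cell-type
  signal by design.
* **RNase-R pairs.** Six treated/mock pairs (matching the experimental
  design the pipeline targets) with independent library sizes; enrichment
  acts on expected counts before sampling — true circles ×5, artifacts ×0.1.
* **Disease cohort.** 27 cases vs 59 controls (the prodromal-vs-control
  contrast sizes), with 10% of host genes scaled by 2^(−1) in cases; all of
  a gene's circles move together, matching gene-level aggregation.
  Covariates are drawn independently of condition so that Wald calibration
  is testable.
* **Reference tables.** Gene sets, a disease–gene table and SNP positions
  with designed signal (per-group sets built from specific-circle host
  genes; half the SNPs within 500 kb of a circle, half > 5 Mb away).

What the generator does **not** model: batch effects, sample-quality
gradients, per-gene dispersion trends, correlated circles within a gene
beyond the shared disease effect, isoform-level linear splicing, or
read-level errors. Passing recovery tests therefore demonstrates the
correctness and calibration of the estimators under the assumed generative
model, not robustness to real-data artifacts.

## Problem sizes and determinism

Tests and the acceptance script run the full default design (500 genes,
≈ 2,000 candidate circles, 47 control samples) for recovery checks and the
standard calibration design (2,000 genes, 20 vs 20 samples, mean 100,
dispersion 0.1, 10% perturbed at log2FC 1) for the NB-Wald checks; unit
tests use smaller instances of the same generator. Every output table
carries a header comment with the tool version, a hash of the effective
configuration and the seed; re-running with identical config and inputs is
byte-identical, which the tests assert file by file.

## Known limitations

* The exclusive/super-host bookkeeping of a real dataset depends on the
  upstream caller's isoform resolution; only the synthetic ground truth is
  reconciled exactly.
* Specificity over three groups is the default; the 5-cell-type mode scores
  finer identities but the mean+s.d. criterion then leans on very few
  samples per type.
* Fold enrichment normalization in the validation filter (per-million) is a
  documented choice; the upstream protocol does not state one.
* The NB model shares one dispersion per gene across conditions and applies
  no shrinkage; very low-count genes therefore have noisy dispersion
  estimates and conservative power.
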