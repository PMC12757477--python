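# Methods

`phosphodiff` analyses paired label-free proteome, phosphopeptide and bulk
transcriptome data from a multi-condition experiment: a control line (LP), a
line expressing a WT kinase transgene (WT), and several lines expressing
activating variants ("mutants"). This note documents the statistical
procedures, the synthetic-data model used to validate them, and the design
choices made where the methodology was genuinely open.

## Differential expression

Real studies produce differential-expression tables with dedicated tools
(DESeq2 for RNA-Seq counts, Progenesis-style ANOVA for label-free MS); those
tables enter this pipeline as inputs. For self-contained synthetic runs,
`diffexpr.standin_test` provides a simple two-group test on log2 abundances:

* log2FC = log2((mean_test + ε) / (mean_ref + ε)), with ε defaulting to half
  the smallest positive value in the table (avoids −∞ without distorting
  large abundances);
* p-values from a **pooled-variance normal test**: the per-feature pooled
  variance is averaged over all features and used as a known variance. The
  replicate noise model in label-free and RNA-Seq-like data is a shared
  multiplicative CV, which is exactly the regime in which variance sharing
  is correct — and it is how DESeq2/limma obtain power at n = 3. A
  per-feature Welch t at 3 vs 3 has ~2–4 degrees of freedom; measured on
  the synthetic study it retains only 40–60 % of planted effects after BH
  correction, which would make every per-mutant intersection analysis
  unusable. Per-feature Student and Welch tests remain available via
  `var_mode`.
* Benjamini–Hochberg adjustment across features.

DEPs/DEGs are features with adjusted p < 0.05 **and** |log2FC| ≥ 0.585
(fold change ≥ 1.5). Features significant by p but failing the fold-change
filter stay in the report — both counts are meaningful. The pooled
"allmut" contrast treats all mutant samples as one group versus WT.

## Differential phosphorylation

Phosphopeptide records are first filtered at ptmRS localization score
strictly > 50. Each phosphopeptide is tied to its parent protein; the
phosphopeptide-to-protein ratio per sample (`normalize_phospho`) is
scale-free in per-sample normalization factors.

**Strategy 1 (normalized-difference outlier scan).** For each mutant
condition, A = parent-protein log2FC and B = phosphopeptide log2FC
(condition vs WT). An OLS trend of B on A is fitted and its intercept
subtracted from B, so the corrected trend passes through the origin
(Theil–Sen available via `robust=True`). The statistic

    D = (max(A, B) − min(A, B)) / (A + B)

is zero when phosphorylation simply follows expression and grows when the
two diverge. Peptides with |A + B| < 1e−6 are excluded (not clamped: the
ratio is undefined there, and clamping would manufacture outliers).
Outliers are peptides whose Iglewicz–Hoaglin modified Z-score of D is ≥ 1
(the published, deliberately permissive threshold; configurable).
B is taken from the raw phosphopeptide abundance, not the protein-normalized
value: the null of "phosphorylation tracks expression" is B ≈ A, which is
what the symmetric D statistic and the diagonal null population of the
scatter assume. A `use_normalized` flag exposes the alternative.

**Modified Z-score.** z = 0.6745·(x − median)/MAD; if MAD = 0 the fallback
(x − median)/(1.253314·meanAD) is used; an all-equal vector yields zeros.
The implementation is tested against a numpy-free brute-force oracle on all
integer vectors of length ≤ 7 over {0,1,2,3}.

**Strategy 2 (all-pairs ratio test).** Per peptide and condition, all
n_mut × n_wt ratios of phosphopeptide abundance (and, separately, of parent
protein abundance) are formed, shifted by +1, log2-transformed and
averaged; the effect is log2FC_phospho − log2FC_tot and the p-value comes
from an equal-variance Student t between the two transformed ratio sets
(Welch via flag), Bonferroni-corrected over every peptide × condition test
in the run (the most conservative family). The subtraction of log2FC_tot
is itself the protein-level correction; forming the phospho ratios from
*already protein-normalized* values and then subtracting would remove the
protein contribution twice and mis-call every peptide of a regulated
protein. Zero-variance degenerate sets: p = 1 if the means agree, 0
otherwise.

*Known limitation — calibration.* The all-pairs construction produces 12
ratios from only 7 underlying replicates. A t-test that treats them as
independent understates the variance of the mean difference by roughly
2.5×, so the test is anticonservative under the null: across null
simulations the Bonferroni-corrected family-wise error is ~0.6, not 0.05.
This is a property of the published procedure, reproduced deliberately. The
pipeline's protection against these false positives is the consensus tier,
not the Bonferroni correction alone.

*Pseudocount.* The +1 on ratios means log2(r+1) is not odd in log r, so
the effect is **not** antisymmetric under swapping mutant and control;
antisymmetry is recovered only in the small-pseudocount limit
(`pseudocount_ratio`).

**Consensus.** A peptide flagged by both strategies and detected in at
least two mutant conditions is a *high-confidence* call; anything flagged
once is a *candidate*. On the synthetic study the consensus has observed
FDR ≈ 0 at sensitivity ≥ 0.9, while strategy 1 alone at Z ≥ 1 flags ~15–20 %
of null peptides per condition (as its permissive threshold dictates).

## Proteome–transcriptome concordance

DEPs are matched to transcripts through an explicit two-column protein→gene
mapping file; duplicate mappings are an error (ambiguity must be visible,
never resolved silently). The modified Z-score is computed independently on
the protein and RNA fold-change vectors; a pair is an outlier if |z| ≥ 3.5
on either axis (single pass, not iterated). Pearson r is reported for the
survivors together with the same-direction count (a pair with either fold
change exactly 0 counts as discordant, since 0 has no sign).

## Metagene gain/loss-of-function classification

For the genes differentially expressed in *every* mutant-vs-WT contrast,
the per-gene unweighted mean of mutant log2FCs is compared with the
LP-vs-WT log2FC:

* **LoF** — mean mutant effect < 0 and a real negative LP-vs-WT effect:
  the WT transgene activates the gene and the mutants have lost that
  activation;
* **GoF** — mean mutant effect > 0 with no real LP-vs-WT effect:
  activation specific to the mutant forms;
* anything else is unclassified.

"Real LP effect" means adjusted p < 0.05 **and** |log2FC| ≥ the near-zero
band (default 0.2). A magnitude-only band was rejected: with 3 vs 3
replicates at CV 0.2 the LP-vs-WT estimate has a standard deviation of
~0.23, so ~40 % of genes with a true zero LP effect would fall outside a
0.2 band by noise alone and be misclassified. Each subset (down/up) is also
tested in aggregate: two-sided one-sample t of the mean mutant effects and
of the LP effects against zero (zero-variance input gives p = 1; subsets
smaller than 3 are reported as not computable).

## ORA, bubble-term selection and TF-target clustering

ORA is the hypergeometric upper tail P[X ≥ k] with X ~ HG(N, K, n) over a
configurable universe, BH-adjusted across tested sets; sets with zero
overlap are omitted. Bubble-plot selection: (i) sort by adjusted p;
(ii) same-named terms across source databases keep the smallest adjusted p;
(iii) term pairs with overlap-gene Jaccard ≥ 0.75 collapse to the larger
(higher-K, more general) set; a user-supplied exclusion list may drop
domain-irrelevant terms — relevance is never inferred automatically.

The TF-target matrix encodes "gene i is an annotated target of TF j" as
0/1, restricted to TFs present in the proteome or transcriptome
("expressed") and to DEGs with at least one retained regulator. Both axes
are clustered hierarchically with average linkage on 1 − Pearson r;
constant rows/columns (correlation undefined) get the maximal distance 2;
rows and columns are sorted lexicographically first, making the result
deterministic and invariant to input order. The gene tree is cut into k
(default 2) flat clusters.

## PPI network

The induced subgraph of the PPI edge list on the union of the role sets
(DEPs, consensus DPhospho parents, kinases/phosphatases, TFs, seeds), with
self-loops dropped and duplicate/reversed edges collapsed; isolated nodes
keep degree 0. Hubs are ranked by plain degree (ties lexicographic);
confidence scores may filter edges (`min_score`) but never weight degree.

## Synthetic data model

`simulate.SimulationConfig` defaults define the study: conditions LP, WT,
T1, T5, T12, T15, Q79KW80R; 3 replicates each (4 for the WT proteome);
2000 proteins, 5000 transcripts, 60 phosphopeptides; 10 % planted DEPs and
DEGs; 25 % planted differentially phosphorylated peptides; effect size 2
on the log2 scale; replicate CV 0.2 (log2 noise sd = √log(1+cv²)/log 2);
20 % of DEPs concordant with a same-direction DEG; 40 GoF and 40 LoF genes;
29 TFs in two planted modules.

Generator structure worth knowing when interpreting test results:

* Baselines are log-normal (log2 mean 20, sd 2 for proteins); noise is
  multiplicative Gaussian on the log scale. Missingness is optional MCAR
  (default 0); intensity-dependent missingness is deliberately out of
  scope so that planted truth stays recoverable.
* Planted directions are balanced exactly and magnitudes jittered
  uniformly in [0.75, 1.25] × effect. A point-mass at ±effect would be an
  artifact: median/MAD outlier screens treat a discrete minority mode as a
  block of outliers, which no continuous real fold-change distribution
  produces. A concordant DEG inherits its DEP's signed magnitude.
* Phosphopeptide abundance = parent protein × site stoichiometry × noise,
  so protein-level normalization is exactly the right inverse on
  non-planted peptides. Planted peptides get an upward effect_log2 shift in
  a random subset (≥ 2) of mutant conditions while their parents are left
  unshifted; non-planted peptides draw half their parents from planted
  DEPs so that the protein correction is genuinely exercised. ptmRS scores
  are drawn so planted records always pass the > 50 filter, while some
  non-planted records fail it.
* LoF genes are elevated in WT only (so mutant-vs-WT and LP-vs-WT are both
  negative); GoF genes are elevated in mutants only. TF modules 1 and 2
  target the down- and up-regulated DEG groups respectively (80 % within
  module, 5 % across), plus one unexpressed decoy TF that the expression
  filter must drop. The PPI graph is Erdős–Rényi over DEPs ∪ phospho
  parents ∪ TFs with one designated hub wired to half the nodes.

What passing tests on this generator do **not** show about real data:
calibration under heteroscedastic or intensity-dependent noise, robustness
to missingness not-at-random, identifier-mapping noise, or ratio
compression in label-free quantification — none of which are simulated.

## Problem sizes and numerical choices

Multi-seed experiments (`experiments.py`, the test suite and the
acceptance script) run a scaled-down study — 300 proteins, 900
transcripts, 40 phosphopeptides, 10 TFs, 25 GoF/LoF genes — with all
fractions, effect sizes, noise and replicate structure at the defaults;
per-feature power does not depend on feature count, so recovery statistics
transfer. Floating-point output is written at 12 significant digits;
re-running any stage with the same seed reproduces outputs byte-for-byte.
Average-linkage ties and hub-degree ties break lexicographically.
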