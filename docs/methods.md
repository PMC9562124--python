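# Methods

`npcg` implements the desk-side statistics of a two-group study that
profiles the same animals with whole-genome bisulfite sequencing (WGBS)
and bulk RNA-seq — the canonical design being four in-vitro-produced
(IVP) versus four in-vivo (MOET) calves — and asks which genes respond
in either or both molecular layers. This note records the models, the
numerical choices, and what the synthetic data do and do not establish.

## Differential methylation

Input is a per-CpG table of methylated/total read counts per sample.
Cells with coverage below 10 reads or above the sample's 99.9th
empirical coverage percentile (linear-interpolation quantile) are
masked as low-coverage or clonal; a site is kept only if unmasked in
**every** sample, so each retained site has a complete design.

Each site is tested by a grouped-binomial logistic regression of
(methylated, unmethylated) on the group indicator, optionally plus a
centred age covariate. Significance comes from the likelihood-ratio
test of the group term against chi-square with 1 df; at four samples
per group with proportions near 0 or 1 the LRT is markedly stabler
than the Wald test. Fits use IRLS with linear predictors clipped at
±30, which bounds the estimate under complete separation instead of
diverging; rows whose fit degenerates are flagged and reported with
p = 1 rather than raising. q-values are Benjamini–Hochberg (a
registration hook accepts alternative q-value estimators, e.g. a
SLIM-style method); DMC are sites with q < 0.05, labelled hyper- or
hypomethylated by the sign of the group log-odds coefficient.

**Known caveat.** The binomial model ignores between-replicate
overdispersion. On beta-binomial null data the LRT is anti-conservative,
increasingly so as the overdispersion correlation ρ grows; the test
suite asserts this monotonicity rather than hiding it. Beta-binomial
dispersion modelling is deliberately out of scope.

## Differential expression

Counts are normalised with DESeq-style median-of-ratios size factors:
`sf_j = exp(median_g(log c_gj − log GM_g))` over genes with no zero in
any sample (the log-space median, matching DESeq2/pydeseq2 exactly).
Each gene is fitted with an NB2 GLM — log link, offset `log sf_j`,
design intercept + group (+ optional age) — and the group coefficient
is tested two-sided by Wald with observed-information standard errors.
BH controls the FDR over tested genes; all-zero genes get NA p-values
and do not count toward the number of tests.

Two small-sample choices matter and were made as follows:

* **Dispersion** is estimated per gene by maximising the Cox–Reid
  adjusted profile likelihood (the −½ log det X'WX correction used by
  edgeR/DESeq2), floored at 1e-8 and capped at 100. Plain profile ML
  is biased low when two or three mean parameters are fitted to 8–16
  observations, which alone inflates the null rejection rate past 7%;
  the CR adjustment recovers the simulated truth nearly unbiasedly. No
  shrinkage across genes is applied.
* **Reference distribution**: the Wald statistic is referred to t with
  n − p degrees of freedom rather than the normal. At n = 8/8 this
  moves the null rejection rate at 0.05 from ≈0.070 to ≈0.047, and at
  4/4 from ≈0.10 to ≈0.057; it converges to the normal as n grows.

Optimisation alternates batched IRLS for the mean with a golden-section
search for the dispersion on log α (budget 50 alternations, relative
log-likelihood tolerance 1e-8; convergence is declared when the
likelihood stops improving beyond tolerance). All genes are fitted
simultaneously with shared-design vectorised linear algebra, which is
what makes full refitting inside the permutation engine affordable.

The a-posteriori power estimator simulates two-group NB data from a
user spec (gene means, dispersions, fold change, π₀), runs the full
test + BH pipeline, and reports the detected fraction of truly-DE
genes with a binomial CI.

## Annotation

Coordinates: BED intervals are 0-based half-open; CpG positions 1-based
(Bismark coverage dialect); conversion happens only at the I/O
boundary. A promoter is TSS ± 1000 bp with **both endpoints included**
(a site exactly 1000 bp away is inside; 1001 bp is out). Shores are
2000 bp flanks on each side of a CpG island, excluding the island.
Every site is assigned its nearest TSS by absolute distance with no
cutoff; equidistant ties go to the smaller coordinate, then the
lexicographically smaller gene id; strand is ignored for distance.
Structure labels follow the precedence promoter > exon > intron >
intergenic (promoter-first when a site is both, the convention of the
usual annotation tools), and island > shore > open sea. Introns are
derived as gene body minus exons.

## Nonparametric combination (NPC)

Features are matched at gene level: a gene's methylation signal is its
CpG counts pooled over all sites whose nearest TSS is that gene (an
alternative Šidák-adjusted min-p reduction over site-level tests is
available behind a flag); only genes present in both omics enter.

Per gene, two partial p-values are computed under a group labelling:
the binomial-logistic LRT on the pooled counts and the NB Wald test on
expression (size factors fixed, dispersion re-estimated per labelling —
samples, not residuals, are exchangeable under the null). They are
combined with Fisher's statistic T = −2(ln p_meth + ln p_expr), with
zero p-values floored at the smallest positive double before the log.

The null distribution of T comes from relabelling the samples and
applying the **same** labels to both omics. Joint permutation is the
defining feature: it preserves the dependence between the two data
layers, so the combined test stays valid when methylation and
expression of the same animals are correlated — which is exactly the
situation the coupling in the data creates. The test suite demonstrates
the converse: permuting each omic independently inflates the type-I
error on correlated null data (≈0.065–0.077 at nominal 0.05 in the
configurations exercised) while joint permutation stays at or below
nominal.

With n₁ + n₂ samples there are C(n₁+n₂, n₁) distinct labelings; when
that number is within the permutation budget B (default 1000) they are
enumerated exhaustively and `p = #{T ≥ T_obs}/C` including the observed
labelling, making the p-value exact. For 4 vs 4 that is 70 assignments;
since two-sided partial tests give identical statistics on
complementary labelings, the smallest attainable p is 2/70 ≈ 0.029 —
below the 0.05 NPCG threshold, so calling remains possible at this
design size. When C > B, B distinct non-identity labelings are sampled
without replacement (seeded) and the add-one estimate
(1 + #{T_b ≥ T_obs})/(B + 1) is reported. Under independent omics at
larger n, T follows chi-square with 4 df; the acceptance suite checks
the KS distance on 5000 null genes.

NPCG are genes with combined p < 0.05; each carries the sign of its
observed expression group effect.

## Clustering, ordination, enrichment

NPCG expression (log1p of size-factor-normalised counts, gene-wise
median-centred — the transform is a package choice, stated because the
upstream convention is not pinned anywhere) is clustered
agglomeratively on d = 1 − Spearman ρ with centroid linkage, computed
by the Lance–Williams recurrence on squared distances. Zero-variance
profiles get average ranks and are defined to have correlation 0.
Centroid linkage can produce inversions; they are permitted, and the
k-cluster cut is defined on the merge sequence (state before the last
k − 1 merges), not on a height threshold. Distance ties break by
lexicographic gene-pair order, so dendrogram, leaf order and text
exports are byte-stable. A quadratic-time direct centroid-distance
formula serves as the test oracle for the recurrence.

Sample QC ordination is a plain SVD PCA of the centred (optionally
log-normalised) matrix. Set overlaps report exclusive Venn-region
counts. Over-representation of a gene list against named gene sets
uses the one-sided hypergeometric tail with BH across sets — this is
deliberately minimal plumbing, not a replacement for a full functional-
annotation service.

## Pathway model

For a declared gene set, all (gene, sample) observations are pooled
into one long table — duplicate ids have methylation averaged and
counts averaged then rounded half-away-from-zero — and fitted with a
single NB regression

log E[count] = β₀ + β_meth·MP + β_group·1[group] (+ β_int·MP·1[group]),

MP being the per-gene methylation proportion on the 0–1 scale (percent
axes are display only). If the interaction's p ≥ 0.05 it is dropped
and the model refitted; the reported fit then has no interaction term.
The default pools genes without a gene term, matching a single
per-pathway model over all member genes; a gene-level intercept option
exists behind a flag. Prediction curves are exp of the linear predictor
on the MP grid 0.10–0.90 (step 0.10) plus each group's sample-average
MP, and are strictly positive by construction.

## Synthetic data

The generator is first-class, tested code, and its defaults define the
study conditions everything else is verified under: two groups of
n = 4; ~2000 CpGs and ~400 genes tiled on one synthetic chromosome
(non-overlapping gene bodies, 1–3 exons each, CpG islands over half the
promoters); coverage Poisson(30) truncated at ≥ 1; beta-binomial
methylated counts parameterised by (mean, ρ) with α = μ(1−ρ)/ρ,
β = (1−μ)(1−ρ)/ρ and ρ = 0.05; per-CpG baseline logits uniform on
[−2, 2] (spanning the 10–90% proportion range the pathway curves
cover); a +2 logit shift at 10% of sites; NB counts with mean 100,
dispersion 0.1, log2 fold change 1 at 10% of genes; and a coupling of
γ = −1 per unit methylation proportion on the log expression scale,
applied to the **realised** per-gene methylation so the pathway model
can recover γ from observable data. Coverage is truncated at ≥ 1 so
every simulated site is observed; the coverage filter is exercised with
separately planted low/high-coverage sites. Sample sizes, noise levels
and seeds make every generator a pure function of (seed, config) with
byte-identical outputs.

What the synthetic data do **not** emulate: genome-scale feature
counts, realistic LD-like spatial correlation between neighbouring
CpGs, CHG/CHH contexts, isoform structure, GC/length biases, batch or
latent factors, and the real study's effect-size distributions (which
were never published). Passing tests therefore establish correctness
and calibration of the machinery — exact permutation validity,
parameter recovery, oracle agreement — not that any particular gene
list from the original animals would be reproduced.

Where tests need other regimes they say so explicitly: calibration
checks use ρ = 0 (the binomial tests are only calibrated without
overdispersion); the chi-square-limit check uses n = 10/10 with
independent omics; the joint-vs-independent permutation demonstration
uses a strongly coupled null (γ = −3, ρ = 0.5, NB dispersion 0.02,
coverage 100) chosen so the cross-omics correlation of the partial
p-values is ≈0.5 and the contrast between the two permutation schemes
is visible above Monte-Carlo noise.

## Problem sizes

The default verification sizes — 2000 genes for calibration runs, 5000
for the distributional check, 1000 for the permutation-scheme
comparison, 100 replicates for pathway recovery — were chosen so each
check pins its quantity well inside the asserted band (Monte-Carlo SE
a few times smaller than the tolerance) while the whole suite stays
desk-scale. Exhaustive 4-vs-4 NPC on 2000 genes refits ~140,000 GLMs
per run; the batched IRLS makes this a couple of minutes.

## Limitations

* The DMC test inherits the binomial model's anti-conservativeness
  under overdispersion (documented and asserted, not corrected).
* Per-gene dispersion without cross-gene shrinkage is noisier than
  DESeq2-style moderation at n = 4; the NPC stage compensates by
  calibrating through permutation rather than through the parametric
  reference.
* Age adjustment is a regression covariate, not latent-factor removal;
  surrogate-variable estimation is out of scope.
* The min-p methylation reduction is a convenience alternative; its
  Šidák correction assumes independent sites, which neighbouring CpGs
  violate.
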