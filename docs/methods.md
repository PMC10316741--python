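# Methods

## The model of a cross-stage methylation change

A probe's methylation fraction β is compared across three disease stages
of one tissue: Normal (N), Precancerous lesion (P), Cancer (C). Two
contrasts anchor everything: P/N and C/N, both with Normal as reference.
A probe is differentially methylated (DMP) in a contrast when

* Δβ = mean(case) − mean(reference) satisfies |Δβ| > `delta_thresh`
  (default 0.1 — a tenth of the methylation scale, the conventional
  biological-relevance floor for array data), and
* the Benjamini–Hochberg adjusted p of a two-sided Welch two-sample
  *t*-test on β is below `alpha` (default 0.05).

The test runs on the β scale, not M-values. Rationale: the effect
threshold is stated on the β scale, group sizes are ≥ 18–20 where the
Welch *t* is robust to the mild heteroscedasticity of β values, and every
downstream quantity (Δβ, trajectory gates) is a β difference. BH is
applied per contrast over all probes surviving preprocessing — the
universe *M* — not per chromosome. Welch rather than a moderated
(empirical-Bayes-shrunk) *t* keeps the statistic self-contained; with
tens of samples per group, variance moderation changes little. A probe
with zero variance in both groups and equal means gets p = 1, not NaN.

### Eight trajectory types

With Δβ_CP = mean(C) − mean(P) and t = `delta_thresh`, a probe that is a
P/N DMP is typed:

| P/N | C/N | extra gate | type | group |
|-----|-----|-----------|------|-------|
| hyper | hyper | Δβ_CP > t | 1 hyper-hyper | sHyperMethyl |
| hyper | hyper | Δβ_CP ≤ t | 2 hyper-similar | sHyperMethyl |
| hyper | none | — | 3 hyper-normal | transient |
| hyper | hypo | — | 4 hyper-hypo | reversed |
| hypo | hypo | Δβ_CP < −t | 5 hypo-hypo | sHypoMethyl |
| hypo | hypo | Δβ_CP ≥ −t | 6 hypo-similar | sHypoMethyl |
| hypo | none | — | 7 hypo-normal | transient |
| hypo | hyper | — | 8 hypo-hyper | reversed |

Probes that are not P/N DMPs get no type — the scheme is anchored on the
precancerous lesion, so tumour-only changes fall outside it by design.
Three open edges were closed as follows. (a) A probe hyper in both
contrasts whose tumour level sits *below* precancer by more than t is
folded into type 2 ("similar") so the classification stays an exhaustive
partition. (b) "Back to normal in the tumour" (types 3/7) means the C/N
call is `none` — it failed the Δβ or the FDR gate — with no separate
equivalence band. (c) The C/P gate of types 1/5 is magnitude-only; no
significance test is attached to it. The classifier is verified
exactly against an independently coded brute-force decision table.

## Enrichment

**Chromosome.** The null distribution of per-autosome DMP counts comes
from drawing D = |DMP set| probe ids uniformly without replacement from
the universe of M filtered probes, `n_perm` = 10,000 times. Empirical
p-values use the pseudocount form (1 + #{replicates ≥ observed}) /
(n_perm + 1), which cannot return 0 and is the standard permutation-p
estimator. Sex chromosomes are excluded from the categories (their β
distribution tracks sample sex) but remain in the universe drawn from.
Because a category's count under this null is exactly hypergeometric,
the Monte-Carlo p is testable against the analytic tail; the suite
asserts agreement within 3 Monte-Carlo standard errors.

**Genomic features / CGI relation.** Exact hypergeometric tails per
category (both tails inclusive of the observed count), BH across
categories. This is probe-label resampling, the natural analogue of
interval-based genomic association testing for array probes, where the
"regions" are the manifest's own annotation classes. A probe annotated
to several gene-model features counts once per distinct feature.

**Gene sets.** One-sided hypergeometric over an explicit gene universe —
the genes represented on the filtered array — rather than an annotation-
wide default universe, which would overstate enrichment for array
content. A probe contributes all its manifest genes; a gene enters a
query once however many of its probes were selected. Sets are filtered
to 10–500 genes within the universe (smaller sets are unstable, larger
ones uninformative); BH across tested sets. The implementation's tail is
checked against one-sided Fisher exhaustively on all 2×2 tables with
N ≤ 50.

**Bidirectional chaos.** A category significant (adjusted p < α) in both
the sHyperMethyl-derived and the sHypoMethyl-derived enrichment of the
same tissue: one pathway pushed in both directions at once. Cross-tissue
comparison classifies each significant (pathway, tissue, direction) with
precedence bidirectional-within-tissue → different-direction-shared →
same-direction-shared → unique.

**Top-k ranking** (for pathway queries restricted to the most confident
sites) sorts by raw P/N p ascending, ties by |Δβ| descending, then probe
id — fully deterministic.

## Oncogene/TSG mapping

Only shared-group probes (types 1/2/5/6) are mapped. Manifest features
collapse to three regions: TSS200 ∪ TSS1500 → TSS, 5'UTR ∪ 3'UTR → UTR,
Body ∪ 1stExon → Body; intergenic probes map nowhere. 1stExon goes with
Body, not the promoter: the promoter-proximal classes are the two TSS
windows, and first-exon methylation behaves like gene-body methylation
more often than like promoter methylation. A probe annotated to several
gene-feature pairs contributes one hit per pair whose gene is in the
census. Cross-tissue recurrence keeps (gene, region, group) combinations
seen in ≥ `min_tissues` tissues (default 2).

## Survival screen

One univariate Cox proportional-hazards fit per probe, continuous β as
the covariate (no median split — dichotomization discards information
and the cut would be cohort-dependent). The partial-likelihood Newton
solve is vectorized across probes with the Breslow convention for tied
event times and was verified against R's `coxph(ties="breslow")` to
seven digits and against lifelines on tie-free data. The reported p is
the likelihood-ratio test against coefficient 0; it depends only on the
rank order of times, hence is invariant to time-unit changes. The screen
thresholds *raw* p < α: it is a screening step whose per-type fractions
are the object of interest, not a discovery list, and the companion
fraction summary is interpreted against the α floor. Constant probes get
p = 1 by convention. Per-type summaries report the fraction of each
trajectory type's probes passing the screen, optionally restricted to a
subset (e.g., sites recurring in several tissues).

## Synthetic cohorts

The generator emulates the three-stage design the pipeline assumes and
is itself first-class, tested code.

* **Noise model.** β ~ Beta(μφ, (1−μ)φ) per probe, sample and stage;
  variance μ(1−μ)/(φ+1) reproduces the mean–variance coupling of real
  beta values and respects [0, 1]. Default concentration φ = 100 gives
  sd ≈ 0.05 at μ = 0.45, a realistic bulk-array noise level. Stage means
  are clipped to [0.01, 0.99] before parameterization.
* **Design.** Defaults 20/20/40 samples for N/P/C — cancer arms of
  public cohorts run larger than their controls — and baseline mean 0.45
  (bulk tissue genome-wide average; 0.18 mimics a hypomethylated
  cervix-like tissue). Planted probes of type k shift P and C means by
  the type's effect pair; the default pairs use |Δβ| = 0.3 with a 0.15
  C-stage overshoot for types 1/5, and are validated at construction
  against the noiseless decision table (a pair implying a different type
  is a config error).
* **Annotation.** Autosome assignment by approximate chromosome-length
  weights; genes round-robin over a synthetic pool (4 probes/gene);
  feature and CGI classes by fixed proportions (45 % Body, 20 %
  intergenic, 30 % island, …). Gene sets are random draws, except
  planted sets that take a stated number of genes from the
  hyper-planted and hypo-planted pools — the ground truth for
  bidirectional-chaos detection. A census table labels a random 20 % of
  genes oncogene/TSG/both.
* **Survival.** Cancer-arm event times are exponential with log hazard
  Σ coef·β over the planted prognostic probes; censoring is independent
  exponential with its rate matched to the target censored fraction.
  Planted prognostic probes get a per-patient mean uniform on baseline
  ± 0.45 in the Cancer arm: prognostic CpGs separate patients across a
  wide span of the β scale, and a hazard effect per unit β is only
  detectable if β actually varies between patients. The spread is wide
  enough that a log-HR of 2 is found with power ≈ 0.999 at n = 200 and
  50 % censoring (score-test calculation). These probes remain null for
  the stage contrasts (their mean equals baseline).
* **Determinism.** One `numpy` Generator seeded from the config drives
  every draw in fixed order; identical configs give byte-identical
  artifacts.

What the generator does **not** model: probe-type (I/II) chemistry and
its bias, batch effects, cell-composition mixtures (dispersion is folded
into φ), correlated neighbouring probes, and non-proportional hazards.
Passing tests therefore demonstrate the statistical machinery is correct
and calibrated under the stated noise model — not that real cohorts meet
that model.

## Numerical and scale choices

* Imputation: row-mean default (deterministic, order-independent); KNN
  (k = 5, squared-Euclidean over mutually observed probes, mean of the
  k nearest donors) provided. Observed cells are never altered.
* Quantile normalization maps each sample's sorted values onto the
  across-sample mean order statistics; stable tie-breaking makes it
  idempotent to < 1e-12. Default is `none`: every downstream statistic
  is a within-probe contrast, so across-sample quantile forcing is
  opt-in.
* Group CV uses the population (n-denominator) standard deviation.
* Cox Newton: 50 iterations max, steps clipped to ±2 to damp early
  overshoot, convergence at |step| < 1e-8; zero-information probes
  (constant covariate among at-risk samples) short-circuit to coef 0,
  p 1.
* Test-suite problem sizes — 1,000–3,000-probe universes, 100 planted
  probes per type, 20-seed calibration loops, 10,000-replicate
  permutation and label-permutation oracles — are chosen so every
  statistical assertion has clear margin (Monte-Carlo error well inside
  the asserted tolerance) while the whole suite stays interactive.

## Known limitations

* The missingness filter is the only probe QC; detection-p and
  cross-reactive-probe filtering belong upstream of a beta matrix.
* The Welch test assumes within-group independence; cohorts with
  technical replicates or paired designs need a different model.
* Gene sets are flat: no ontology-graph propagation between terms.
* The survival screen is univariate by construction; joint prognostic
  effects are attenuated in per-probe estimates (visible in the planted
  examples), and multivariate model building is out of scope.
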