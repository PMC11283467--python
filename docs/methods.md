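# Methods

## Canonical fusion records and dialects

A fusion call is an *ordered* 5'→3' gene pair with breakpoints, strand, and
read support split into junction-spanning (`split_reads`) and encompassing
(`discordant_pairs`) counts; `total_support` is their sum. Order matters
throughout: chromosome accounting distinguishes the two partners, so pairs
are never sorted, and X–Y and Y–X are distinct events. Coordinates are
1-based fully closed, as the modeled callers emit them; no 0-based
conversion happens anywhere. Chromosomes are normalized to chr1–chr22,
chrX, chrY; rows on other contigs are skipped and counted, as are rows with
malformed numerics or unrecoverable gene fields. Multi-symbol gene fields
("A,B") resolve to the first listed symbol — a deterministic,
caller-order-respecting rule; callers do not document how such ambiguity
should be reconciled, so this is a design choice, not a caller contract.

## Filter cascade and consensus

Per-call filters, in fixed order (they commute — each is a pure predicate —
but the order is fixed for reproducibility; consensus must come last):

| filter | rule | default |
|---|---|---|
| support | keep `total_support ≥ t` and `split_reads ≥ s` | t = 3, s = 1 |
| read-through | drop flagged calls; fallback: same chromosome, same strand, 0 < pos3 − pos5 ≤ gap | gap = 50 kb |
| blacklist | drop ordered pairs in any list, or calls touching a banned gene | user lists |
| consensus | keep pairs called by ≥ k distinct callers in a sample | k = 2 of 3 |

Consensus matches at the ordered gene-pair level and ignores breakpoint
coordinates, because callers rarely agree on the exact junction; support is
aggregated as the per-field **max** across callers (they see the same
physical reads, so summing would double-count). Duplicate rows for the same
(sample, caller, pair) — isoform junctions — collapse to the per-field max
first. Burden is the count of distinct ordered pairs per sample; samples
with no surviving event count 0.

## Catalog, classification and chromosome accounting

The cohort catalog holds unique ordered pairs with their carrier-sample
count. *Recurrent* means carried by ≥ 2 cohort samples (configurable);
*known* means the ordered pair occurs in a supplied curated database, by
exact symbol equality — alias resolution is cohort-specific curation and is
deliberately out of scope. The 2×2 classification table reports counts and
percentages of the grand total, rounded half-up to one decimal, as printed
tables are.

Chromosome accounting uses the counted-twice convention: an intrachromosomal
fusion adds 2 to its chromosome's intra column; an interchromosomal fusion
adds 1 to each partner's inter column, so column totals always equal twice
the number of fusions counted. Both a `unique` (one count per catalog
entry, the default) and a `per_sample` (weighted by carrier count)
multiplicity are provided, since published per-chromosome tables do not
always say which they use.

## Survival analysis

*Dichotomization.* The threshold at quantile q is the smallest observed
value with at least q·n of the values at or below it; a sample is **high**
only if strictly above it. Ties go low, so on continuous data the high
group is always the strict minority (e.g. exactly 4 of 10 distinct values at
q = 0.6). The threshold is always computed on the full analyzed cohort,
never per subgroup, so all subgroup analyses share one cutoff.

*Kaplan–Meier.* Standard product-limit estimator over distinct event times,
with subjects censored at an event time remaining at risk for that factor.
Variance is Greenwood's; the t-month survival rate is S at the last event
time ≤ t, with a 95% CI on the complementary log-log scale
(S^exp(±z·se), se = √var / (S·|log S|)), clipped to [0,1]. Degenerate
cases (no events yet, S ∈ {0,1}, zero variance) return point intervals.

*Log-rank.* k-group O−E statistic with hypergeometric covariance summed
over distinct event times, referred to χ²(k−1); no continuity correction;
no events at all gives statistic 0, p = 1. Note the statistic is *not*
invariant to adding a censored subject after the last event time — such a
subject joins every risk set; it is invariant to one censored strictly
before the first event time, and the tests assert exactly that.

*Cutoff scan.* For each quantile in {0.1, …, 0.9} the cohort is
dichotomized and a two-arm log-rank run in every subgroup; a cell with an
empty arm is untestable and excluded from coverage rather than counted as a
failure. The selected quantile maximizes the number of subgroups with
p < α (α = 0.05); ties break by the smaller all-patients p, then the
smaller quantile. The default subgroup set is all patients, the four IHC
subtypes, and intrinsic subtypes, each requiring at least 15 samples — tiny
panels (e.g. a 5-patient normal-like group) are too small for a meaningful
two-arm log-rank and only add noise to coverage.

Because the subgroups are heavily nested (the all-patients panel contains
every subtype; TNBC and basal-like overlap almost completely) and nine
quantiles are scanned, coverage-at-selection is a maximum over ~80
correlated 5%-level tests: even under a true null, about half of simulated
cohorts show some quantile covering ≥ 2 subgroups, although each individual
cell's type-I error is calibrated (~5%). The scan is a cutoff-*selection*
heuristic, not a calibrated test; any inference on the selected cutoff
should be validated on independent data.

*Rank tests and FDR.* Group comparisons use the two-sample Wilcoxon
rank-sum (exact p for small tie-free samples, normal approximation with
average ranks otherwise) and Kruskal–Wallis, via scipy; multiplicity
adjustment is Benjamini–Hochberg (statsmodels), with the adjustment scope
(per panel vs joint) left to the caller.

## Immune enrichment

The per-sample score of a gene set S ranks genes by expression within the
sample (average ranks on ties) and walks them from highest to lowest,
accumulating Σᵢ [P_in(i) − P_out(i)], where P_in is the ECDF of S weighted
by rank^α and P_out the unweighted ECDF of the complement. α = 0.25, the
conventional ssGSEA exponent (configurable); α = 0 reduces to an unweighted
two-sample rank comparison. The walk breaks rank ties by gene symbol, so
scores are independent of the matrix's row order, and the statistic is
invariant under any strictly increasing per-sample transform of expression.
Scores are comparable within a cohort only — which the 60th-percentile
high/low grouping respects; no cross-cohort normalization is attempted, and
no stromal/purity companion score is computed. At least two set genes must
be present in the matrix.

## Synthetic cohort

The generator replaces the controlled-access patient data and defines the
conditions under which the pipeline is validated.

**Cohort structure.** 300 tumors; IHC subtype proportions 51.2% TNBC,
22.6% HR+HER2−, 14.1% HR+HER2+, 12.1% HR−HER2+; intrinsic subtype drawn
conditional on IHC class (TNBC mostly basal-like, HR+HER2− mostly luminal,
HER2+ mostly HER2-enriched). True burden per sample is negative binomial
(dispersion 3) with per-intrinsic-subtype means 1.5 (normal-like), 6
(luminal A), 9 (luminal B and HER2-enriched), 10 (basal-like) — echoing the
ordering and magnitude of published per-subtype medians, with an overall
mean near 8–9 and filtered medians landing in the 5–11 range.

**Gene universe and fusion identity.** A fixed 400-symbol universe with
deterministic chromosome assignment, over-weighting chr1 and chr17, and 2 Mb
spacing within a chromosome, so genuine fusions never trip the positional
read-through heuristic. 60% of drawn pairs are intrachromosomal. A
300-pair recurrent pool (drawn with probability 0.4 per event) creates
cohort-level recurrence; 10% of events come from a curated "known" list, so
known fusions are mostly private — together these reproduce a catalog that
is roughly 78% private / 21% recurrent and ~14% known.

**Caller behaviour.** Per-caller sensitivities 0.95 / 0.90 / 0.60 (caller A
detects the most fusions), independent per caller; 5% of true per-caller
observations are drawn weak (no split read, or total support < 3) so the
support filter is exercised on true calls. Artifact classes per sample
(Poisson expectations): 2 read-throughs (half flagged, half positional, all
well-supported and multi-caller — the read-through filter must do the
work), 1.5 blacklist pairs (well-supported, multi-caller), 2 low-support
single-caller junk calls.

**Survival.** Event times are exponential with baseline hazard 0.0037 per
month (5-year EFS ≈ 0.80 in the low arm) and hazard ratio 3.0 on the arm
above the 0.6 quantile of *true* burden; censoring is uniform on (0, b)
with b solved numerically so the expected censoring fraction is 0.20.

**Expression.** 600 genes × samples, log-normal TPM (per-gene log2 mean
N(4, 1.5), residual SD 1); a 40-gene immune set is shifted down by 1 log2
unit in high-burden samples.

**What the simulation does not capture.** Breakpoint-level caller
disagreement beyond positional jitter; expression-dependent detection
sensitivity; correlated caller errors; gene-length and GC structure in the
expression matrix; non-proportional hazards and informative censoring; real
immune-signature covariance. Passing the recovery tests therefore shows the
pipeline's statistics behave as designed under their own model assumptions,
not that the biological findings would replicate on a real cohort.

## Numerical choices and degenerate inputs

Percentages round half-up to one decimal. All-tied values at
dichotomization put every sample in the low group with a warning. Empty
catalogs give zero counts and 0.0 percentages. Quantiles in burden
summaries use the linear-interpolation rule. The Greenwood accumulation
skips terms where all at-risk subjects fail (S = 0 gets variance 0). The
simulator keeps every random draw inside one seeded `numpy` generator; a
config + seed pair reproduces bundles byte for byte.

## Problem sizes used in the test and acceptance suites

Oracle-equivalence checks run on 500 random small instances (≤ 45 calls, 5
samples); the permutation null uses 20,000 relabellings at n = 60; scan
calibration uses 50 planted-effect and 100 null cohorts at n = 300; immune
recovery uses 50 planted and 50 null cohorts at n = 150 with the 600-gene
matrix; type-I calibration of the rank tests uses 2,000 replicates. These
sizes make the whole suite run in a few minutes on one CPU while keeping
Monte-Carlo error well inside the asserted margins.
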