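# fusionburden

Tools for asking whether the number of gene fusions in a tumor transcriptome
carries prognostic information. Bulk RNA-seq fusion callers disagree with
each other and produce abundant artifacts, so a single caller's output is a
poor burden estimate; this package implements the consensus workflow used in
early breast-cancer cohort studies and everything downstream of it:

1. **Harmonization** — read per-sample output tables from three caller
   dialects (Arriba-like, STAR-Fusion-like, STAR-SEQR-like) into one
   canonical record (5'→3' gene pair, breakpoints, split/discordant read
   support, artifact flags).
2. **Filter cascade** — drop calls with fewer than 3 supporting reads or no
   split read, read-through artifacts (flagged, or same-chromosome
   same-strand within 50 kb), and "red herring" gene pairs from
   healthy-tissue / homology blacklists; then keep only gene pairs called by
   **≥2 of 3** callers in a sample.
3. **Fusion burden** — the count of distinct fusion events per sample — and
   the cohort catalog: private vs recurrent (≥2 carrier samples), known vs
   unknown (curated database pairs), and per-chromosome inter/intra
   accounting in which every fusion is counted twice, once per partner gene.
4. **Survival** — Kaplan–Meier event-free survival with Greenwood variance
   and complementary log-log confidence intervals, the k-group log-rank
   test, and a cutoff scan that dichotomizes burden at each quantile
   q ∈ {0.1, …, 0.9} (high = strictly above the empirical quantile) and
   selects the quantile whose split separates survival in the most
   subgroups.
5. **Immune enrichment** — a per-sample ssGSEA-style score: with genes
   ranked by expression within a sample, the score is Σᵢ [P_in(i) − P_out(i)],
   where P_in is the rank^α-weighted ECDF of the gene set (α = 0.25) and
   P_out the unweighted ECDF of the remaining genes, walked from highest to
   lowest expression.

Real cohorts of this kind are controlled-access, so the package ships a
seeded synthetic-cohort generator (`fusionburden.synthetic_cohort`) that
emulates the whole study: multi-caller call files with caller-specific
sensitivity and artifact classes, subtype-dependent negative-binomial
burden, exponential EFS with a hazard ratio planted on the high-burden arm,
and an expression matrix whose immune signal shifts with burden. Every
stage is tested against this generator's ground truth.

## Worked example

```sh
python analysis/01_simulate_cohort.py   # writes results/cohort/
python analysis/02_filter_consensus.py
python analysis/03_annotate_catalog.py
python analysis/04_burden_survival.py
python analysis/05_immune_enrichment.py
```

With the default seed the chain prints (abridged):

```
read 9893 calls (0 rows skipped); median raw calls per sample by caller: {'A': 12.0, 'B': 11.0, 'C': 8.0}
support filter:        943 removed, 8950 kept
read-through filter:  1386 removed, 7564 kept
blacklist filter:     1145 removed, 6419 kept
2-of-3 consensus:    2484 per-sample events
median fusion burden after filtering: 7.0

1625 unique fusions from 2484 per-sample events
                    unknown            known              sum
   private     1123 (69.1%)       139 (8.6%)     1262 (77.7%)
 recurrent      271 (16.7%)        92 (5.7%)      363 (22.3%)
       sum     1394 (85.8%)      231 (14.2%)    1625 (100.0%)

selected cutoff quantile: 0.5 (threshold 7.0 fusions), covering 7 subgroups at p<0.05
5-year EFS, all patients (n=300): 71.1% (95% CI 0.655, 0.759)
  all   high burden (n=145): 5Y-EFS 60.3%
  all   low  burden (n=155): 5Y-EFS 81.0%
all: median immune score high-burden -53.8 vs low-burden 27.8 (Wilcoxon p = 1.26e-27)
```

Reading these numbers: the three callers report a median of 8–12 raw calls
per sample; after the cascade the median burden is 7 distinct events. Most
catalog entries are private and unknown. The cutoff scan picks the quantile
separating event-free survival in the most subgroups; patients above the
threshold have markedly worse 5-year EFS and lower immune enrichment —
the direction and rough magnitude of the effects planted by the simulator
(hazard ratio 3 on the high-burden arm, negative immune shift).

## Layout

- `src/fusionburden/` — the library: `caller_io`, `fusion_filter`,
  `fusion_annotate`, `burden_survival`, `immune_enrichment`,
  `synthetic_cohort`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and acceptance suites (oracle-based:
  brute-force enumeration, permutation nulls, hand-computed statistics,
  lifelines cross-checks).
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
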