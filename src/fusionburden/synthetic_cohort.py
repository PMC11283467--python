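"""Seeded generator of a synthetic multi-caller fusion study bundle.

Real cohorts of this kind are controlled-access, so every pipeline stage is
exercised against simulated data whose ground truth is known.  A bundle
contains per-sample caller files in the three supported dialects, a clinical
table with event-free survival, a TPM expression matrix with an immune gene
set, blacklist and known-fusion lists, and a machine-readable truth record.

What is emulated
----------------
* a breast-cancer-like cohort: four IHC subtypes, intrinsic subtypes
  conditional on IHC class, and negative-binomial per-sample fusion burden
  whose per-subtype means echo the published medians (normal-like lowest,
  basal-like highest);
* caller behaviour: per-caller sensitivity, per-caller support-count noise,
  a configurable fraction of weak (sub-threshold) true observations, and
  three artifact classes (read-throughs, blacklist "red herrings" and
  low-support single-caller junk);
* survival: exponential event times with a hazard ratio planted on the
  high-burden group (dichotomized at the configured quantile of true
  burden) and independent uniform censoring calibrated to the configured
  censoring fraction;
* expression: log-normal TPM with the immune gene set shifted down in
  high-burden samples.

The gene universe is a fixed synthetic symbol list with assigned
chromosomes, over-weighting chr1 and chr17 so the chromosome accounting is
exercised on a skewed distribution; genes on a chromosome are spaced 2 Mb
apart so genuine fusions never trip the positional read-through heuristic.

All randomness flows through a single seeded ``numpy`` generator; the same
config and seed reproduce byte-identical bundles.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .burden_survival import SUBTYPES, dichotomize_quantile
from .caller_io import (CALLERS, CHROMOSOMES, FusionCall, GenePairList,
                        write_caller_table, write_gene_pair_list)
from .immune_enrichment import GeneSet

INTRINSIC = ("LumA", "LumB", "HER2E", "Basal", "Normal")


def _default_subtype_proportions() -> dict[str, float]:
    # cohort composition of a neoadjuvant-heavy early-BC series
    return {"TNBC": 0.512, "HR+HER2-": 0.226, "HR+HER2+": 0.141, "HR-HER2+": 0.121}


def _default_intrinsic_mix() -> dict[str, dict[str, float]]:
    return {
        "TNBC":     {"Basal": 0.85, "HER2E": 0.08, "LumB": 0.02, "LumA": 0.02, "Normal": 0.03},
        "HR+HER2-": {"LumA": 0.55, "LumB": 0.25, "Normal": 0.10, "Basal": 0.05, "HER2E": 0.05},
        "HR+HER2+": {"LumB": 0.35, "HER2E": 0.35, "LumA": 0.20, "Basal": 0.05, "Normal": 0.05},
        "HR-HER2+": {"HER2E": 0.70, "Basal": 0.15, "LumB": 0.10, "Normal": 0.05, "LumA": 0.0},
    }


def _default_burden_mean() -> dict[str, float]:
    # per-intrinsic-subtype negative-binomial means, echoing published medians
    return {"Normal": 1.5, "LumA": 6.0, "LumB": 9.0, "HER2E": 9.0, "Basal": 10.0}


def _default_caller_sensitivity() -> dict[str, float]:
    # caller A detects the most fusions, C the fewest
    return {"A": 0.95, "B": 0.90, "C": 0.60}


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort.

    Rates are per sample and in expectation; survival times are in months.
    """

    n_samples: int = 300
    subtype_proportions: dict[str, float] = field(default_factory=_default_subtype_proportions)
    intrinsic_mix: dict[str, dict[str, float]] = field(default_factory=_default_intrinsic_mix)
    burden_mean: dict[str, float] = field(default_factory=_default_burden_mean)
    burden_dispersion: float = 3.0
    caller_sensitivity: dict[str, float] = field(default_factory=_default_caller_sensitivity)
    # artifact classes (expected counts per sample)
    read_through_rate: float = 2.0
    blacklist_rate: float = 1.5
    low_support_rate: float = 2.0
    frac_low_support_true: float = 0.05
    # support-count model for confident calls
    split_mean: float = 6.0
    discordant_mean: float = 4.0
    # catalog structure
    n_universe_genes: int = 400
    intra_prob: float = 0.6
    recurrent_pool_size: int = 300
    p_recurrent: float = 0.4
    n_blacklist_pairs: int = 40
    n_blacklist_genes: int = 4
    known_pool_fraction: float = 0.1
    n_known_extra: int = 400
    p_known_private: float = 0.1
    # survival model
    baseline_hazard: float = 0.0037       # per month; 5-year S ~ 0.80 in the low arm
    hazard_ratio_high: float = 3.0
    censoring_fraction: float = 0.2
    burden_quantile: float = 0.6
    # expression model
    n_expr_genes: int = 600
    immune_set_size: int = 40
    immune_shift: float = 1.0             # log2-TPM downshift of set genes, high-burden arm

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if abs(sum(self.subtype_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("subtype proportions must sum to 1")
        for mix in self.intrinsic_mix.values():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError("intrinsic mix must sum to 1 per subtype")
        if self.hazard_ratio_high <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazard parameters must be positive")
        if not 0 <= self.censoring_fraction < 1:
            raise ValueError("censoring_fraction must be in [0, 1)")
        for rate in (self.read_through_rate, self.blacklist_rate, self.low_support_rate):
            if rate < 0:
                raise ValueError("artifact rates must be non-negative")
        if not 0 <= self.frac_low_support_true <= 1:
            raise ValueError("frac_low_support_true must be in [0, 1]")


@dataclass
class SyntheticCohort:
    """In-memory bundle: caller calls, clinical table, expression, lists, truth."""

    config: CohortConfig
    calls: list[FusionCall]
    clinical: pd.DataFrame
    expression: pd.DataFrame
    gene_set: GeneSet
    blacklists: list[GenePairList]
    known_dbs: list[GenePairList]
    truth: dict


# ---------------------------------------------------------------------------
# Gene universe
# ---------------------------------------------------------------------------

def gene_universe(n_genes: int) -> pd.DataFrame:
    """Deterministic synthetic gene list: symbol, chromosome, position, strand.

    Chromosomes are assigned round-robin with chr1 and chr17 over-weighted;
    genes on the same chromosome sit 2 Mb apart.
    """
    cycle = list(CHROMOSOMES) + ["chr1", "chr17", "chr17"]
    rows = []
    per_chrom: dict[str, int] = {}
    for i in range(n_genes):
        chrom = cycle[i % len(cycle)]
        k = per_chrom.get(chrom, 0)
        per_chrom[chrom] = k + 1
        rows.append({
            "symbol": f"GENE{i:04d}",
            "chrom": chrom,
            "pos": 2_000_000 * (k + 1),
            "strand": "+" if i % 2 == 0 else "-",
        })
    return pd.DataFrame(rows)


class _PairSampler:
    """Draws ordered gene pairs from the universe, honoring the intra-
    chromosomal bias and a forbidden set (blacklist, already-used pairs)."""

    def __init__(self, universe: pd.DataFrame, intra_prob: float,
                 banned_pairs: frozenset, banned_genes: frozenset):
        self.symbols = universe["symbol"].to_numpy()
        self.loc = {r.symbol: (r.chrom, int(r.pos), r.strand)
                    for r in universe.itertuples()}
        self.by_chrom = {c: np.flatnonzero((universe["chrom"] == c).to_numpy())
                         for c in universe["chrom"].unique()}
        self.allowed = np.flatnonzero(
            ~universe["symbol"].isin(banned_genes).to_numpy())
        self.intra_prob = intra_prob
        self.banned_pairs = banned_pairs
        self.banned_genes = banned_genes
        self.universe = universe

    def draw(self, rng: np.random.Generator, exclude: set = frozenset()) -> tuple[str, str]:
        for _ in range(10_000):
            i = int(rng.choice(self.allowed))
            g5 = self.symbols[i]
            if rng.random() < self.intra_prob:
                chrom = self.universe["chrom"].iat[i]
                candidates = self.by_chrom[chrom]
            else:
                candidates = self.allowed
            j = int(rng.choice(candidates))
            if j == i:
                continue
            g3 = self.symbols[j]
            if g3 in self.banned_genes:
                continue
            pair = (g5, g3)
            if pair in self.banned_pairs or pair in exclude:
                continue
            return pair
        raise RuntimeError("could not draw a valid gene pair")


# ---------------------------------------------------------------------------
# Sample-level draws
# ---------------------------------------------------------------------------

def _draw_samples(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sample ids, IHC subtype, intrinsic subtype and true fusion burden."""
    subs = list(config.subtype_proportions)
    p_subs = np.array([config.subtype_proportions[s] for s in subs])
    rows = []
    for i in range(config.n_samples):
        subtype = str(rng.choice(subs, p=p_subs / p_subs.sum()))
        mix = config.intrinsic_mix[subtype]
        intr = list(mix)
        p_intr = np.array([mix[s] for s in intr])
        intrinsic = str(rng.choice(intr, p=p_intr / p_intr.sum()))
        mean = config.burden_mean[intrinsic]
        r = config.burden_dispersion
        burden = int(rng.negative_binomial(r, r / (r + mean)))
        rows.append({"sample_id": f"S{i:04d}", "subtype": subtype,
                     "intrinsic": intrinsic, "true_burden": burden})
    return pd.DataFrame(rows)


def _support(rng: np.random.Generator, config: CohortConfig, weak: bool) -> tuple[int, int]:
    """Split/discordant read counts; confident draws always pass the default
    filter (split >= 2, total >= 3), weak draws always fail it."""
    if weak:
        if rng.random() < 0.5:
            return 0, 3 + int(rng.poisson(2.0))          # no split read
        return 1, int(rng.integers(0, 2))                # total support < 3
    split = 2 + int(rng.poisson(max(config.split_mean - 2.0, 0.1)))
    disc = 1 + int(rng.poisson(max(config.discordant_mean - 1.0, 0.1)))
    return split, disc


# ---------------------------------------------------------------------------
# Survival and expression
# ---------------------------------------------------------------------------

def _censor_upper_bound(hazards: np.ndarray, frac: float) -> float:
    """Upper bound b of U(0, b) censoring giving the target censoring
    fraction in expectation for a mixture of exponential event times."""

    def p_censored(b: float) -> float:
        x = hazards * b
        return float(np.mean(-np.expm1(-x) / x))

    return brentq(lambda b: p_censored(b) - frac, 1e-9, 1e9, xtol=1e-9, rtol=1e-12)


def generate_survival(groups: Mapping[str, str], config: CohortConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Exponential EFS times with the configured hazard ratio on the high
    arm and independent uniform censoring.

    Returns a DataFrame with sample_id, efs_months, efs_event.
    """
    samples = list(groups)
    lam = np.array([config.baseline_hazard *
                    (config.hazard_ratio_high if groups[s] == "high" else 1.0)
                    for s in samples])
    event_t = rng.exponential(1.0 / lam)
    if config.censoring_fraction > 0:
        bound = _censor_upper_bound(lam, config.censoring_fraction)
        censor_t = rng.uniform(0.0, bound, size=len(samples))
        efs = np.minimum(event_t, censor_t)
        event = event_t <= censor_t
    else:
        efs = event_t
        event = np.ones(len(samples), dtype=bool)
    return pd.DataFrame({"sample_id": samples,
                         "efs_months": np.round(efs, 3),
                         "efs_event": event})


def generate_expression(groups: Mapping[str, str], config: CohortConfig,
                        rng: np.random.Generator) -> tuple[pd.DataFrame, GeneSet]:
    """Log-normal TPM matrix whose immune-set genes are shifted down in
    high-burden samples."""
    samples = list(groups)
    genes = [f"EXPR{i:04d}" for i in range(config.n_expr_genes)]
    set_idx = rng.choice(config.n_expr_genes, size=config.immune_set_size, replace=False)
    in_set = np.zeros(config.n_expr_genes, dtype=bool)
    in_set[set_idx] = True
    mu = rng.normal(4.0, 1.5, size=config.n_expr_genes)
    log2 = mu[:, None] + rng.normal(0.0, 1.0, size=(config.n_expr_genes, len(samples)))
    high = np.array([groups[s] == "high" for s in samples])
    log2[np.ix_(in_set, high)] -= config.immune_shift
    expr = pd.DataFrame(2.0 ** log2, index=genes, columns=samples)
    gene_set = GeneSet(name="immune_synthetic",
                       genes=frozenset(genes[i] for i in set_idx))
    return expr, gene_set


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> SyntheticCohort:
    """Generate the full in-memory study bundle; reproducible from the seed."""
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    universe = gene_universe(config.n_universe_genes)
    loc = {r.symbol: (r.chrom, int(r.pos), r.strand) for r in universe.itertuples()}

    # blacklists: ordered pairs plus a few single genes banned outright
    bl_genes = frozenset(str(s) for s in rng.choice(
        universe["symbol"].to_numpy(), size=config.n_blacklist_genes, replace=False))
    free_sampler = _PairSampler(universe, config.intra_prob,
                                banned_pairs=frozenset(), banned_genes=bl_genes)
    bl_pairs: set[tuple[str, str]] = set()
    while len(bl_pairs) < config.n_blacklist_pairs:
        bl_pairs.add(free_sampler.draw(rng, exclude=bl_pairs))
    blacklist_pairs = GenePairList("blacklist_pairs", pairs=frozenset(bl_pairs))
    blacklist_genes = GenePairList("blacklist_genes", single_genes=bl_genes)

    # true-fusion machinery avoids everything the blacklist would remove
    sampler = _PairSampler(universe, config.intra_prob,
                           banned_pairs=frozenset(bl_pairs), banned_genes=bl_genes)
    pool: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    while len(pool) < config.recurrent_pool_size:
        pair = sampler.draw(rng, exclude=seen)
        pool.append(pair)
        seen.add(pair)

    # known DB: a slice of the recurrent pool plus extra curated pairs that
    # individual samples can hit privately
    n_known_pool = int(round(config.known_pool_fraction * len(pool)))
    known_idx = rng.choice(len(pool), size=n_known_pool, replace=False)
    known: set[tuple[str, str]] = {pool[i] for i in known_idx}
    while len(known) < n_known_pool + config.n_known_extra:
        known.add(sampler.draw(rng, exclude=known | seen))
    known_db = GenePairList("known_fusions", pairs=frozenset(known))
    known_extra = sorted(known - set(pool))

    samples = _draw_samples(config, rng)
    callers = list(CALLERS)
    sens = config.caller_sensitivity

    calls: list[FusionCall] = []
    truth_samples: dict[str, dict] = {}
    for row in samples.itertuples():
        sid = row.sample_id
        true_pairs: set[tuple[str, str]] = set()
        while len(true_pairs) < row.true_burden:
            u = rng.random()
            if u < config.p_recurrent:
                pair = pool[int(rng.integers(len(pool)))]
                if pair in true_pairs:
                    continue
            elif u < config.p_recurrent + config.p_known_private and known_extra:
                pair = known_extra[int(rng.integers(len(known_extra)))]
                if pair in true_pairs:
                    continue
            else:
                pair = sampler.draw(rng, exclude=true_pairs)
            true_pairs.add(pair)

        n_artifacts = {"read_through": int(rng.poisson(config.read_through_rate)),
                       "blacklist": int(rng.poisson(config.blacklist_rate)),
                       "low_support": int(rng.poisson(config.low_support_rate))}

        for pair in sorted(true_pairs):
            (c5, p5, s5), (c3, p3, s3) = loc[pair[0]], loc[pair[1]]
            for caller in callers:
                if rng.random() >= sens[caller]:
                    continue
                weak = rng.random() < config.frac_low_support_true
                split, disc = _support(rng, config, weak)
                calls.append(FusionCall(
                    sample_id=sid, caller=caller, gene5=pair[0], gene3=pair[1],
                    chrom5=c5, chrom3=c3,
                    pos5=p5 + int(rng.integers(0, 500)), pos3=p3 + int(rng.integers(0, 500)),
                    strand5=s5, strand3=s3, split_reads=split, discordant_pairs=disc))

        # read-through artifacts: close same-strand neighbours, half flagged
        for _ in range(n_artifacts["read_through"]):
            chrom = str(rng.choice([c for c, idx in sampler.by_chrom.items() if len(idx) >= 2]))
            i, j = rng.choice(sampler.by_chrom[chrom], size=2, replace=False)
            g5, g3 = universe["symbol"].iat[int(i)], universe["symbol"].iat[int(j)]
            if (g5, g3) in true_pairs or g5 in bl_genes or g3 in bl_genes:
                continue
            flagged = bool(rng.random() < 0.5)
            pos5 = int(loc[g5][1])
            pos3 = pos5 + int(rng.integers(1_000, 45_000))
            split, disc = _support(rng, config, weak=False)
            for caller in callers:
                if rng.random() < sens[caller]:
                    calls.append(FusionCall(
                        sample_id=sid, caller=caller, gene5=g5, gene3=g3,
                        chrom5=chrom, chrom3=chrom, pos5=pos5, pos3=pos3,
                        strand5="+", strand3="+", split_reads=split,
                        discordant_pairs=disc, read_through=flagged))

        # blacklist hits: well-supported, multi-caller, but listed as red herrings
        bl_list = sorted(bl_pairs)
        for _ in range(n_artifacts["blacklist"]):
            pair = bl_list[int(rng.integers(len(bl_list)))]
            (c5, p5, s5), (c3, p3, s3) = loc[pair[0]], loc[pair[1]]
            split, disc = _support(rng, config, weak=False)
            for caller in callers:
                if rng.random() < sens[caller]:
                    calls.append(FusionCall(
                        sample_id=sid, caller=caller, gene5=pair[0], gene3=pair[1],
                        chrom5=c5, chrom3=c3, pos5=p5, pos3=p3,
                        strand5=s5, strand3=s3,
                        split_reads=split, discordant_pairs=disc))

        # low-support junk: weak single-caller calls
        for _ in range(n_artifacts["low_support"]):
            pair = sampler.draw(rng, exclude=true_pairs)
            (c5, p5, s5), (c3, p3, s3) = loc[pair[0]], loc[pair[1]]
            split, disc = _support(rng, config, weak=True)
            caller = str(rng.choice(callers))
            calls.append(FusionCall(
                sample_id=sid, caller=caller, gene5=pair[0], gene3=pair[1],
                chrom5=c5, chrom3=c3, pos5=p5, pos3=p3,
                strand5=s5, strand3=s3, split_reads=split, discordant_pairs=disc))

        truth_samples[sid] = {
            "subtype": row.subtype, "intrinsic": row.intrinsic,
            "true_pairs": sorted(map(list, true_pairs)),
            "burden": len(true_pairs),
            "artifacts": n_artifacts,
        }

    true_burden = {sid: truth_samples[sid]["burden"] for sid in truth_samples}
    groups, threshold = dichotomize_quantile(true_burden, config.burden_quantile)
    for sid, g in groups.items():
        truth_samples[sid]["group"] = g

    survival = generate_survival(groups, config, rng)
    clinical = samples.drop(columns=["true_burden"]).merge(survival, on="sample_id")
    expression, gene_set = generate_expression(groups, config, rng)

    truth = {
        "samples": truth_samples,
        "burden_threshold": threshold,
        "burden_quantile": config.burden_quantile,
        "survival": {
            "baseline_hazard": config.baseline_hazard,
            "hazard_ratio_high": config.hazard_ratio_high,
            "censoring_fraction": config.censoring_fraction,
        },
        "immune_shift": config.immune_shift,
        "seed": int(seed),
    }
    return SyntheticCohort(config=config, calls=calls, clinical=clinical,
                           expression=expression, gene_set=gene_set,
                           blacklists=[blacklist_pairs, blacklist_genes],
                           known_dbs=[known_db], truth=truth)


def simulate_burden_survival(config: CohortConfig | None = None, seed: int = 0
                             ) -> tuple[dict[str, int], pd.DataFrame, dict]:
    """Lightweight path for survival studies: true burdens, clinical table
    and truth, without simulating caller files or expression."""
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    samples = _draw_samples(config, rng)
    burden = dict(zip(samples["sample_id"], samples["true_burden"].astype(int)))
    groups, threshold = dichotomize_quantile(burden, config.burden_quantile)
    survival = generate_survival(groups, config, rng)
    clinical = samples.drop(columns=["true_burden"]).merge(survival, on="sample_id")
    truth = {"groups": groups, "burden_threshold": threshold,
             "burden_quantile": config.burden_quantile}
    return burden, clinical, truth


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

def write_bundle(cohort: SyntheticCohort, outdir) -> Path:
    """Write the bundle to disk (deterministic bytes for a given cohort)."""
    outdir = Path(outdir)
    calls_dir = outdir / "calls"
    calls_dir.mkdir(parents=True, exist_ok=True)
    by_key: dict[tuple[str, str], list[FusionCall]] = {}
    for c in cohort.calls:
        by_key.setdefault((c.sample_id, c.caller), []).append(c)
    for sid in cohort.clinical["sample_id"]:
        for caller in CALLERS:
            write_caller_table(by_key.get((sid, caller), []),
                               calls_dir / f"{sid}.{caller}.tsv", caller)
    cohort.clinical.to_csv(outdir / "clinical.csv", index=False)
    cohort.expression.to_csv(outdir / "expression.tsv", sep="\t",
                             float_format="%.6g", index_label="gene")
    with open(outdir / "immune_gene_set.txt", "w") as fh:
        fh.write("\n".join(sorted(cohort.gene_set.genes)) + "\n")
    write_gene_pair_list(cohort.blacklists[0], outdir / "blacklist_pairs.tsv", "pairs")
    write_gene_pair_list(cohort.blacklists[1], outdir / "blacklist_genes.tsv", "genes")
    write_gene_pair_list(cohort.known_dbs[0], outdir / "known_fusions.tsv", "pairs")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return outdir


def read_bundle_calls(bundle_dir) -> tuple[list[FusionCall], int]:
    """Read all per-sample caller files of a bundle back into canonical calls.

    Returns the calls and the total number of skipped rows.
    """
    from .caller_io import read_caller_table

    calls: list[FusionCall] = []
    skipped = 0
    for path in sorted(Path(bundle_dir, "calls").glob("*.tsv")):
        sid, caller, _ = path.name.rsplit(".", 2)
        result = read_caller_table(path, caller, sid)
        calls.extend(result.calls)
        skipped += len(result.skipped)
    return calls, skipped
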