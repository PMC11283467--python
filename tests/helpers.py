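"""Independent brute-force oracles used by the test suite.

Everything here is written from the definitions — predicate scans, explicit
enumeration, definitional formulas — deliberately sharing no code with the
package implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np

from fusionburden.caller_io import CALLERS, CHROMOSOMES, FusionCall

GENES = ["FBXL20", "BCAS3", "ERBB2", "IKZF3", "ESR1", "NTRK1", "TP53", "PIK3CA"]


def random_calls(rng: np.random.Generator, n: int, n_samples: int = 4,
                 flagged_frac: float = 0.15) -> list[FusionCall]:
    """Random small call instances covering every filter branch."""
    calls = []
    for _ in range(n):
        g5, g3 = rng.choice(GENES, size=2, replace=False)
        calls.append(FusionCall(
            sample_id=f"s{rng.integers(n_samples)}",
            caller=str(rng.choice(CALLERS)),
            gene5=str(g5), gene3=str(g3),
            chrom5=str(rng.choice(CHROMOSOMES[:4])),
            chrom3=str(rng.choice(CHROMOSOMES[:4])),
            pos5=int(rng.integers(1, 200_000)),
            pos3=int(rng.integers(1, 200_000)),
            strand5=str(rng.choice(["+", "-"])),
            strand3=str(rng.choice(["+", "-"])),
            split_reads=int(rng.integers(0, 8)),
            discordant_pairs=int(rng.integers(0, 8)),
            read_through=bool(rng.random() < flagged_frac),
        ))
    return calls


# ---------------------------------------------------------------------------
# Filter / consensus oracles
# ---------------------------------------------------------------------------

def brute_keep(call, cfg, blacklists=()) -> bool:
    """Predicate scan re-stating every per-call filter from its definition."""
    if call.split_reads + call.discordant_pairs < cfg.min_total_support:
        return False
    if call.split_reads < cfg.min_split_reads:
        return False
    if call.read_through and cfg.drop_flagged_read_through:
        return False
    if (call.chrom5 == call.chrom3 and call.strand5 == call.strand3
            and 0 < call.pos3 - call.pos5 <= cfg.read_through_max_gap):
        return False
    for bl in blacklists:
        if (call.gene5, call.gene3) in bl.pairs:
            return False
        if call.gene5 in bl.single_genes or call.gene3 in bl.single_genes:
            return False
    return True


def brute_pipeline(calls, cfg, blacklists=()) -> dict:
    """Enumerate (sample, pair) -> (caller set, max split, max total) for
    pairs surviving all per-call filters and the caller-count consensus."""
    kept = [c for c in calls if brute_keep(c, cfg, blacklists)]
    out = {}
    for s in {c.sample_id for c in kept}:
        for pair in {(c.gene5, c.gene3) for c in kept if c.sample_id == s}:
            sub = [c for c in kept if c.sample_id == s and (c.gene5, c.gene3) == pair]
            callers = frozenset(c.caller for c in sub)
            if len(callers) >= cfg.min_callers:
                out[(s, pair)] = (callers,
                                  max(c.split_reads for c in sub),
                                  max(c.split_reads + c.discordant_pairs for c in sub))
    return out


def consensus_to_dict(fusions) -> dict:
    return {(f.sample_id, (f.gene5, f.gene3)): (f.callers, f.split_reads, f.total_support)
            for f in fusions}


# ---------------------------------------------------------------------------
# Survival oracles
# ---------------------------------------------------------------------------

def brute_km(times, events):
    """Product-limit estimator computed by an explicit loop."""
    times = list(map(float, times))
    events = list(map(bool, events))
    uniq = sorted({t for t, e in zip(times, events) if e})
    surv = []
    s = 1.0
    for u in uniq:
        n = sum(1 for t in times if t >= u)
        d = sum(1 for t, e in zip(times, events) if t == u and e)
        s *= 1.0 - d / n
        surv.append(s)
    return uniq, surv


def brute_logrank_two(times_a, events_a, times_b, events_b):
    """Hand computation of the two-group O/E/V log-rank statistic."""
    ta, ea = list(map(float, times_a)), list(map(bool, events_a))
    tb, eb = list(map(float, times_b)), list(map(bool, events_b))
    uniq = sorted({t for t, e in zip(ta + tb, ea + eb) if e})
    o = e_sum = v = 0.0
    for u in uniq:
        n1 = sum(1 for t in ta if t >= u)
        n2 = sum(1 for t in tb if t >= u)
        d1 = sum(1 for t, ev in zip(ta, ea) if t == u and ev)
        d2 = sum(1 for t, ev in zip(tb, eb) if t == u and ev)
        n, d = n1 + n2, d1 + d2
        o += d1
        e_sum += d * n1 / n
        if n > 1:
            v += d * (n - d) / (n - 1) * (n1 / n) * (1 - n1 / n)
    if v == 0:
        return 0.0
    return (o - e_sum) ** 2 / v


def permutation_logrank_p(times, events, labels, n_perm: int, seed: int) -> float:
    """Permutation null of the two-group log-rank statistic (vectorized).

    Returns P(statistic_perm >= statistic_observed) under random relabelling.
    """
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    lab = np.asarray(labels, int)  # 1 = group A
    uniq = np.unique(t[e])
    at_risk = t[:, None] >= uniq[None, :]          # subjects x times
    died = (t[:, None] == uniq[None, :]) & e[:, None]
    n = at_risk.sum(axis=0).astype(float)
    d = died.sum(axis=0).astype(float)

    def stat(lab_vec):
        n1 = lab_vec @ at_risk
        d1 = lab_vec @ died
        frac = n1 / n
        with np.errstate(invalid="ignore", divide="ignore"):
            e1 = d * frac
            v = np.where(n > 1, d * (n - d) / (n - 1) * frac * (1 - frac), 0.0)
        diff = np.nansum(d1 - e1, axis=-1)
        vv = np.nansum(v, axis=-1)
        return np.where(vv > 0, diff ** 2 / vv, 0.0)

    observed = float(stat(lab.astype(float)))
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, lab.size))
    for i in range(n_perm):
        perms[i] = rng.permutation(lab)
    return float(np.mean(stat(perms) >= observed))


def cloglog_ci(s: float, var: float, conf: float = 0.95):
    """Independent complementary log-log CI computation."""
    from scipy.stats import norm
    z = norm.ppf(0.5 + conf / 2)
    se = math.sqrt(var) / (s * abs(math.log(s)))
    return s ** math.exp(z * se), s ** math.exp(-z * se)


def brute_bh(pvalues):
    """Definitional BH: adj_i = min over k >= rank(i) of m * p_(k) / k."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for rank_pos, i in enumerate(order, start=1):
        candidates = [m * p[order[k - 1]] / k for k in range(rank_pos, m + 1)]
        adj[i] = min(1.0, min(candidates))
    return adj
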