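"""Per-call filter cascade and multi-caller consensus.

The cascade removes likely false positives from raw caller output:

1. support filter — drop calls with total support below a threshold
   (default 3 reads) or without any split read;
2. read-through filter — drop flagged read-throughs, plus a positional
   fallback for unflagged calls joining close same-strand neighbours;
3. blacklist filter — drop gene pairs (or genes) seen in healthy-tissue or
   homology "red herring" lists;
4. consensus — keep only gene pairs called by at least 2 of the 3 callers
   within a sample, merging read support by per-field maximum.

The per-call filters are pure predicates and commute; consensus must run
last.  Consensus matches at the ordered gene-pair level and deliberately
ignores breakpoint coordinates, since callers disagree on exact junctions.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .caller_io import CALLERS, FusionCall, GenePairList


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filter cascade.

    ``min_total_support=3`` and ``min_split_reads=1`` encode "at least three
    supporting reads, at least one of them split"; ``min_callers=2`` is the
    2-of-3 consensus; ``read_through_max_gap`` is the maximum 5'→3' genomic
    gap (bp) for the unflagged read-through heuristic.
    """

    min_total_support: int = 3
    min_split_reads: int = 1
    min_callers: int = 2
    read_through_max_gap: int = 50_000
    drop_flagged_read_through: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.min_callers <= 3:
            raise ValueError("min_callers must be in [1, 3]")
        if min(self.min_total_support, self.min_split_reads, self.read_through_max_gap) < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class ConsensusFusion:
    """A per-sample gene-pair event surviving filters and caller consensus."""

    sample_id: str
    gene5: str
    gene3: str
    chrom5: str
    chrom3: str
    callers: frozenset[str]
    split_reads: int     # max over supporting callers
    total_support: int   # max over supporting callers

    @property
    def intrachromosomal(self) -> bool:
        return self.chrom5 == self.chrom3

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene5, self.gene3)

    def sort_key(self) -> tuple:
        return (self.sample_id, self.gene5, self.gene3)


def filter_support(calls: Iterable[FusionCall], cfg: FilterConfig) -> list[FusionCall]:
    """Keep calls with total_support >= min and split_reads >= min."""
    return [c for c in calls
            if c.total_support >= cfg.min_total_support
            and c.split_reads >= cfg.min_split_reads]


def is_read_through(call: FusionCall, cfg: FilterConfig) -> bool:
    """Read-through predicate: caller flag, or an unflagged same-chromosome,
    same-strand call whose 3' breakpoint lies within ``read_through_max_gap``
    downstream of the 5' breakpoint."""
    if call.read_through and cfg.drop_flagged_read_through:
        return True
    return (call.chrom5 == call.chrom3
            and call.strand5 == call.strand3
            and 0 < call.pos3 - call.pos5 <= cfg.read_through_max_gap)


def filter_read_through(calls: Iterable[FusionCall], cfg: FilterConfig) -> list[FusionCall]:
    """Remove read-through artifacts (flagged, or positional fallback)."""
    return [c for c in calls if not is_read_through(c, cfg)]


def filter_blacklist(calls: Iterable[FusionCall],
                     blacklists: Sequence[GenePairList]) -> list[FusionCall]:
    """Remove calls whose ordered pair, or either gene, is in any blacklist."""
    return [c for c in calls if not any(bl.matches(c) for bl in blacklists)]


def consensus_merge(calls: Iterable[FusionCall], cfg: FilterConfig) -> list[ConsensusFusion]:
    """Collapse per-caller calls to per-sample consensus events.

    Within a sample, calls group by the ordered (gene5, gene3) pair; groups
    carried by at least ``min_callers`` distinct callers become one
    :class:`ConsensusFusion`.  Read support is aggregated by per-field max
    across callers (the same physical reads are typically seen by several
    callers; summing would double-count).  Duplicate rows for the same
    (sample, caller, pair) — e.g. isoform breakpoints — collapse to the
    per-field max first.
    """
    # (sample, pair) -> caller -> [calls]
    grouped: dict[tuple[str, tuple[str, str]], dict[str, list[FusionCall]]] = \
        defaultdict(lambda: defaultdict(list))
    for c in calls:
        grouped[(c.sample_id, c.pair)][c.caller].append(c)

    out: list[ConsensusFusion] = []
    for (sample, pair), by_caller in grouped.items():
        if len(by_caller) < cfg.min_callers:
            continue
        split = max(max(c.split_reads for c in cc) for cc in by_caller.values())
        total = max(max(c.total_support for c in cc) for cc in by_caller.values())
        # chromosome annotation from the best-supported call, ties by caller order
        best = min((c for cc in by_caller.values() for c in cc),
                   key=lambda c: (-c.total_support, c.caller))
        out.append(ConsensusFusion(
            sample_id=sample, gene5=pair[0], gene3=pair[1],
            chrom5=best.chrom5, chrom3=best.chrom3,
            callers=frozenset(by_caller), split_reads=split, total_support=total))
    out.sort(key=ConsensusFusion.sort_key)
    return out


def per_sample_burden(fusions: Iterable[ConsensusFusion],
                      all_samples: Iterable[str] | None = None) -> dict[str, int]:
    """Fusion burden: distinct (gene5, gene3) events per sample.

    ``all_samples`` lists cohort samples that must appear even with zero
    surviving fusions.
    """
    pairs: dict[str, set[tuple[str, str]]] = defaultdict(set)
    for f in fusions:
        pairs[f.sample_id].add(f.pair)
    burden = {s: 0 for s in all_samples} if all_samples is not None else {}
    burden.update({s: len(p) for s, p in pairs.items()})
    return burden


def run_filter_pipeline(calls: Iterable[FusionCall], cfg: FilterConfig,
                        blacklists: Sequence[GenePairList] = ()) -> list[ConsensusFusion]:
    """Full cascade: support → read-through → blacklist → consensus."""
    kept = filter_support(calls, cfg)
    kept = filter_read_through(kept, cfg)
    kept = filter_blacklist(kept, blacklists)
    return consensus_merge(kept, cfg)


CONSENSUS_COLUMNS = ("sample_id", "gene5", "gene3", "chrom5", "chrom3",
                     "callers", "split_reads", "total_support")


def write_consensus_table(fusions: Iterable[ConsensusFusion], path) -> None:
    """Write consensus events to TSV (callers as a ';'-joined set)."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CONSENSUS_COLUMNS)
        for f in sorted(fusions, key=ConsensusFusion.sort_key):
            writer.writerow([f.sample_id, f.gene5, f.gene3, f.chrom5, f.chrom3,
                             ";".join(sorted(f.callers)), f.split_reads,
                             f.total_support])


def read_consensus_table(path) -> list[ConsensusFusion]:
    """Read a TSV written by :func:`write_consensus_table`."""
    import csv

    out: list[ConsensusFusion] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if tuple(header) != CONSENSUS_COLUMNS:
            raise ValueError(f"{path}: not a consensus fusion table")
        for row in reader:
            if not row:
                continue
            out.append(ConsensusFusion(
                sample_id=row[0], gene5=row[1], gene3=row[2],
                chrom5=row[3], chrom3=row[4],
                callers=frozenset(row[5].split(";")),
                split_reads=int(row[6]), total_support=int(row[7])))
    return out
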