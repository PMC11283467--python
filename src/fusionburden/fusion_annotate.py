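"""Cohort-level fusion catalog, classification and chromosome accounting.

From per-sample consensus events this module builds the deduplicated catalog
of unique fusions (ordered gene pairs), annotates each as known (present in a
curated fusion database) or unknown, classifies it as private (one carrier
sample) or recurrent (two or more), cross-tabulates the four classes, and
tallies inter- vs intrachromosomal events per chromosome.

Chromosome accounting follows the double-counting convention: every fusion
contributes two chromosome-level counts, one for each partner gene.  An
intrachromosomal fusion adds 2 to its chromosome's intra column; an
interchromosomal fusion adds 1 to each partner chromosome's inter column.

Printed percentages round half-up to one decimal, matching how such tables
are conventionally typeset.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .caller_io import CHROMOSOMES, GenePairList
from .fusion_filter import ConsensusFusion

RECURRENCE_CLASSES = ("private", "recurrent")
KNOWN_CLASSES = ("unknown", "known")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (as printed tables do), not banker's."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CatalogEntry:
    gene5: str
    gene3: str
    chrom5: str
    chrom3: str
    n_samples: int
    known: bool
    sources: frozenset[str]
    recurrent: bool

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene5, self.gene3)

    @property
    def intrachromosomal(self) -> bool:
        return self.chrom5 == self.chrom3


@dataclass
class CohortCatalog:
    """Deduplicated cohort-level set of unique fusions."""

    entries: list[CatalogEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "gene5": e.gene5, "gene3": e.gene3,
            "chrom5": e.chrom5, "chrom3": e.chrom3,
            "n_samples": e.n_samples, "known": e.known,
            "sources": ";".join(sorted(e.sources)), "recurrent": e.recurrent,
        } for e in self.entries])


def build_catalog(fusions: Iterable[ConsensusFusion],
                  known_dbs: Sequence[GenePairList] = (),
                  recurrent_min_samples: int = 2) -> CohortCatalog:
    """Collapse per-sample consensus events to unique ordered gene pairs.

    ``n_samples`` counts distinct carrier samples; a pair is recurrent when
    carried by at least ``recurrent_min_samples`` samples and known when the
    ordered pair appears in any supplied database (exact symbol match, no
    alias resolution).
    """
    carriers: dict[tuple[str, str], set[str]] = defaultdict(set)
    chroms: dict[tuple[str, str], tuple[str, str]] = {}
    for f in fusions:
        carriers[f.pair].add(f.sample_id)
        chroms.setdefault(f.pair, (f.chrom5, f.chrom3))
    entries = []
    for pair in sorted(carriers):
        sources = frozenset(db.name for db in known_dbs if pair in db.pairs)
        n = len(carriers[pair])
        entries.append(CatalogEntry(
            gene5=pair[0], gene3=pair[1],
            chrom5=chroms[pair][0], chrom3=chroms[pair][1],
            n_samples=n, known=bool(sources), sources=sources,
            recurrent=n >= recurrent_min_samples))
    return CohortCatalog(entries)


@dataclass
class ClassificationTable:
    """2x2 (private|recurrent) x (unknown|known) table with margins.

    ``counts``/``percentages`` are DataFrames indexed by recurrence class;
    percentages are of the grand total, half-up to one decimal.
    """

    counts: pd.DataFrame
    percentages: pd.DataFrame
    row_margins: pd.Series
    row_margin_pct: pd.Series
    col_margins: pd.Series
    col_margin_pct: pd.Series
    total: int

    @classmethod
    def from_counts(cls, private_unknown: int, private_known: int,
                    recurrent_unknown: int, recurrent_known: int) -> "ClassificationTable":
        counts = pd.DataFrame(
            [[private_unknown, private_known], [recurrent_unknown, recurrent_known]],
            index=list(RECURRENCE_CLASSES), columns=list(KNOWN_CLASSES), dtype=int)
        total = int(counts.to_numpy().sum())

        def pct(x: float) -> float:
            return round_half_up(100.0 * x / total) if total else 0.0

        percentages = counts.map(pct)
        row = counts.sum(axis=1)
        col = counts.sum(axis=0)
        return cls(counts=counts, percentages=percentages,
                   row_margins=row, row_margin_pct=row.map(pct),
                   col_margins=col, col_margin_pct=col.map(pct), total=total)

    def to_text(self) -> str:
        lines = [f"{'':>10} " + " ".join(f"{k:>16}" for k in KNOWN_CLASSES) + f" {'sum':>16}"]
        for r in RECURRENCE_CLASSES:
            cells = [f"{self.counts.loc[r, k]} ({self.percentages.loc[r, k]}%)"
                     for k in KNOWN_CLASSES]
            cells.append(f"{self.row_margins[r]} ({self.row_margin_pct[r]}%)")
            lines.append(f"{r:>10} " + " ".join(f"{c:>16}" for c in cells))
        cells = [f"{self.col_margins[k]} ({self.col_margin_pct[k]}%)" for k in KNOWN_CLASSES]
        cells.append(f"{self.total} (100.0%)")
        lines.append(f"{'sum':>10} " + " ".join(f"{c:>16}" for c in cells))
        return "\n".join(lines)


def classification_table(catalog: CohortCatalog) -> ClassificationTable:
    """Cross-tabulate the catalog into the private/recurrent x unknown/known table."""
    cells = {(r, k): 0 for r in RECURRENCE_CLASSES for k in KNOWN_CLASSES}
    for e in catalog.entries:
        r = "recurrent" if e.recurrent else "private"
        k = "known" if e.known else "unknown"
        cells[(r, k)] += 1
    return ClassificationTable.from_counts(
        private_unknown=cells[("private", "unknown")],
        private_known=cells[("private", "known")],
        recurrent_unknown=cells[("recurrent", "unknown")],
        recurrent_known=cells[("recurrent", "known")])


def chromosome_table_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Attach inter/intra percentages (of each chromosome's total, half-up,
    one decimal) to a DataFrame with ``inter`` and ``intra`` columns."""
    out = counts.copy()
    totals = out["inter"] + out["intra"]
    inter_pct, intra_pct = [], []
    for t, inter, intra in zip(totals, out["inter"], out["intra"]):
        if t == 0:
            inter_pct.append(0.0)
            intra_pct.append(0.0)
        else:
            inter_pct.append(round_half_up(100.0 * inter / t))
            intra_pct.append(round_half_up(100.0 * intra / t))
    out["inter_pct"] = inter_pct
    out["intra_pct"] = intra_pct
    return out


def chromosome_table(catalog: CohortCatalog, scope: str = "all",
                     multiplicity: str = "unique") -> pd.DataFrame:
    """Per-chromosome inter/intra fusion counts under the counted-twice rule.

    ``scope`` restricts to known fusions; ``multiplicity`` counts each unique
    catalog entry once (``unique``) or once per carrier sample
    (``per_sample``).
    """
    if scope not in ("all", "known"):
        raise ValueError(f"scope must be 'all' or 'known', got {scope!r}")
    if multiplicity not in ("unique", "per_sample"):
        raise ValueError(f"multiplicity must be 'unique' or 'per_sample', got {multiplicity!r}")
    counts = pd.DataFrame(0, index=list(CHROMOSOMES), columns=["inter", "intra"])
    for e in catalog.entries:
        if scope == "known" and not e.known:
            continue
        w = e.n_samples if multiplicity == "per_sample" else 1
        if e.intrachromosomal:
            counts.loc[e.chrom5, "intra"] += 2 * w
        else:
            counts.loc[e.chrom5, "inter"] += w
            counts.loc[e.chrom3, "inter"] += w
    return chromosome_table_from_counts(counts)


def burden_by_group(burden: Mapping[str, float],
                    labels: Mapping[str, str]) -> pd.DataFrame:
    """Per-group burden summaries: n, median and IQR (25th/75th percentile,
    linear-interpolation quantile rule).  Empty groups are omitted."""
    values: dict[str, list[float]] = defaultdict(list)
    for sample, v in burden.items():
        if sample in labels:
            values[labels[sample]].append(v)
    rows = []
    for group in sorted(values):
        arr = np.asarray(values[group], dtype=float)
        rows.append({
            "group": group, "n": len(arr),
            "median": float(np.median(arr)),
            "q25": float(np.quantile(arr, 0.25)),
            "q75": float(np.quantile(arr, 0.75)),
        })
    return pd.DataFrame(rows).set_index("group") if rows else \
        pd.DataFrame(columns=["n", "median", "q25", "q75"])
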