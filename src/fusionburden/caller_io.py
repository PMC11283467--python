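"""Readers and writers for gene-fusion caller output tables.

RNA-seq fusion callers emit one table per sample, each in its own dialect.
This module understands three dialects — ``A`` (Arriba-like), ``B``
(STAR-Fusion-like) and ``C`` (STAR-SEQR-like) — and maps every data row onto
a single canonical :class:`FusionCall` record, plus a normalized tab-separated
interchange format that round-trips losslessly.

Conventions
-----------
* Coordinates are 1-based and fully closed, as the modeled callers emit them.
* Gene pairs are always ordered 5'→3' ("gene1–gene2"); they are never sorted,
  because downstream chromosome accounting distinguishes the two partners.
* Chromosome names are normalized to the "chr"-prefixed form; rows on
  non-canonical contigs are dropped and counted, never silently ignored.
* Multi-symbol gene fields ("A,B") resolve to the first listed symbol.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

CHROMOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")
CALLERS: tuple[str, ...] = ("A", "B", "C")
STRANDS: tuple[str, ...] = ("+", "-", ".")

#: Column order of the normalized fusion table.
NORMALIZED_COLUMNS: tuple[str, ...] = (
    "sample_id", "caller",
    "gene5", "chrom5", "pos5", "strand5",
    "gene3", "chrom3", "pos3", "strand3",
    "split_reads", "discordant_pairs", "read_through",
)


class DialectError(ValueError):
    """Unknown dialect name or a header that does not match the dialect."""


@dataclass(frozen=True)
class FusionCall:
    """One caller's record of one candidate fusion in one sample.

    ``gene5``/``gene3`` are the 5' and 3' partners (the callers' gene1 and
    gene2); ``split_reads`` counts junction-spanning reads and
    ``discordant_pairs`` counts encompassing read pairs.
    """

    sample_id: str
    caller: str
    gene5: str
    gene3: str
    chrom5: str
    chrom3: str
    pos5: int
    pos3: int
    strand5: str = "."
    strand3: str = "."
    split_reads: int = 0
    discordant_pairs: int = 0
    read_through: bool = False

    def __post_init__(self) -> None:
        if self.caller not in CALLERS:
            raise ValueError(f"unknown caller {self.caller!r}")
        for chrom in (self.chrom5, self.chrom3):
            if chrom not in CHROMOSOMES:
                raise ValueError(f"non-canonical chromosome {chrom!r}")
        for strand in (self.strand5, self.strand3):
            if strand not in STRANDS:
                raise ValueError(f"bad strand {strand!r}")
        if not self.gene5 or not self.gene3:
            raise ValueError("empty gene symbol")
        if self.pos5 < 1 or self.pos3 < 1:
            raise ValueError("positions are 1-based and must be >= 1")
        if self.split_reads < 0 or self.discordant_pairs < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def total_support(self) -> int:
        """Total supporting reads: split reads plus discordant pairs."""
        return self.split_reads + self.discordant_pairs

    @property
    def pair(self) -> tuple[str, str]:
        """Ordered (5', 3') gene-symbol pair."""
        return (self.gene5, self.gene3)

    def sort_key(self) -> tuple:
        return (self.sample_id, self.gene5, self.gene3, self.pos5, self.pos3, self.caller)


@dataclass(frozen=True)
class GenePairList:
    """A named list of gene pairs and/or single genes (blacklist or known DB)."""

    name: str
    pairs: frozenset[tuple[str, str]] = frozenset()
    single_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for g5, g3 in self.pairs:
            if not g5 or not g3:
                raise ValueError("empty symbol in pair list")
        if any(not g for g in self.single_genes):
            raise ValueError("empty symbol in gene list")

    def matches(self, call) -> bool:
        """True if the call's ordered pair, or either partner, is listed."""
        return (call.gene5, call.gene3) in self.pairs or \
            call.gene5 in self.single_genes or call.gene3 in self.single_genes


@dataclass
class SkippedRow:
    line: int          # 1-based line number in the file
    reason: str


@dataclass
class ParseResult:
    """Parsed calls plus per-row skip records (never fatal)."""

    calls: list[FusionCall] = field(default_factory=list)
    skipped: list[SkippedRow] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.calls) + len(self.skipped)


_MULTI_SPLIT = re.compile(r"[,;]")
_PAREN = re.compile(r"\(.*?\)\s*$")


def canonical_gene(raw: str) -> str | None:
    """Canonicalize a caller gene field; None if no symbol can be recovered.

    Handles multi-gene fields ("A,B" → "A"), identifier suffixes
    ("SYM^ENSG..." → "SYM") and trailing parenthetical annotations.
    """
    sym = _MULTI_SPLIT.split(raw.strip())[0]
    sym = sym.split("^")[0]
    sym = _PAREN.sub("", sym).strip()
    return sym or None


def normalize_chrom(raw: str) -> str | None:
    """Normalize a chromosome name to chr-prefixed form; None if non-canonical."""
    name = raw.strip()
    if not name.startswith("chr"):
        name = "chr" + name
    return name if name in CHROMOSOMES else None


# ---------------------------------------------------------------------------
# Dialect definitions.  Each dialect is a fixed header plus row codecs; the
# headers below model the column layout of the corresponding caller family.
# ---------------------------------------------------------------------------

HEADER_A = (
    "#gene1", "gene2", "strand1(gene/fusion)", "strand2(gene/fusion)",
    "breakpoint1", "breakpoint2", "type", "split_reads", "discordant_mates",
    "confidence",
)
HEADER_B = (
    "#FusionName", "JunctionReadCount", "SpanningFragCount",
    "LeftGene", "LeftBreakpoint", "RightGene", "RightBreakpoint",
    "SpliceType", "annots",
)
HEADER_C = (
    "NAME", "JXN_READS", "SPAN_READS",
    "GENE5", "CHROM5", "POS5", "STRAND5",
    "GENE3", "CHROM3", "POS3", "STRAND3", "READ_THROUGH",
)


def _split_breakpoint(text: str, n: int) -> list[str]:
    parts = text.strip().split(":")
    if len(parts) != n:
        raise ValueError(f"malformed breakpoint {text!r}")
    return parts


def _parse_a(row: Sequence[str]) -> dict:
    chrom5, pos5 = _split_breakpoint(row[4], 2)
    chrom3, pos3 = _split_breakpoint(row[5], 2)
    return dict(
        gene5=row[0], gene3=row[1],
        chrom5=chrom5, pos5=int(pos5), strand5=row[2].split("/")[-1],
        chrom3=chrom3, pos3=int(pos3), strand3=row[3].split("/")[-1],
        split_reads=int(row[7]), discordant_pairs=int(row[8]),
        read_through="read-through" in row[6],
    )


def _format_a(c: FusionCall) -> list[str]:
    kind = "deletion/read-through" if c.read_through else (
        "translocation" if c.chrom5 != c.chrom3 else "deletion")
    return [
        c.gene5, c.gene3,
        f"{c.strand5}/{c.strand5}", f"{c.strand3}/{c.strand3}",
        f"{c.chrom5}:{c.pos5}", f"{c.chrom3}:{c.pos3}",
        kind, str(c.split_reads), str(c.discordant_pairs), "high",
    ]


def _parse_b(row: Sequence[str]) -> dict:
    chrom5, pos5, strand5 = _split_breakpoint(row[4], 3)
    chrom3, pos3, strand3 = _split_breakpoint(row[6], 3)
    return dict(
        gene5=row[3], gene3=row[5],
        chrom5=chrom5, pos5=int(pos5), strand5=strand5,
        chrom3=chrom3, pos3=int(pos3), strand3=strand3,
        split_reads=int(row[1]), discordant_pairs=int(row[2]),
        read_through="READTHRU" in row[8],
    )


def _format_b(c: FusionCall) -> list[str]:
    annots = ['"READTHRU"'] if c.read_through else (
        ['"INTERCHROMOSOMAL"'] if c.chrom5 != c.chrom3 else ['"INTRACHROMOSOMAL"'])
    return [
        f"{c.gene5}--{c.gene3}", str(c.split_reads), str(c.discordant_pairs),
        f"{c.gene5}^ENSG00000000000", f"{c.chrom5}:{c.pos5}:{c.strand5}",
        f"{c.gene3}^ENSG00000000000", f"{c.chrom3}:{c.pos3}:{c.strand3}",
        "ONLY_REF_SPLICE", "[" + ",".join(annots) + "]",
    ]


def _parse_c(row: Sequence[str]) -> dict:
    return dict(
        gene5=row[3], gene3=row[7],
        chrom5=row[4], pos5=int(row[5]), strand5=row[6].strip(),
        chrom3=row[8], pos3=int(row[9]), strand3=row[10].strip(),
        split_reads=int(row[1]), discordant_pairs=int(row[2]),
        read_through=row[11].strip().upper() == "TRUE",
    )


def _format_c(c: FusionCall) -> list[str]:
    return [
        f"{c.gene5}--{c.gene3}", str(c.split_reads), str(c.discordant_pairs),
        c.gene5, c.chrom5, str(c.pos5), c.strand5,
        c.gene3, c.chrom3, str(c.pos3), c.strand3,
        "TRUE" if c.read_through else "FALSE",
    ]


_DIALECTS = {
    "A": (HEADER_A, _parse_a, _format_a),
    "B": (HEADER_B, _parse_b, _format_b),
    "C": (HEADER_C, _parse_c, _format_c),
}


def read_caller_table(path, dialect: str, sample_id: str) -> ParseResult:
    """Read one caller output file into canonical :class:`FusionCall` records.

    Rows with an unparseable gene pair, a malformed numeric field or a
    non-canonical chromosome are skipped and recorded in ``result.skipped``;
    parsing never aborts on a bad data row.

    Raises
    ------
    DialectError
        If ``dialect`` is unknown or the file's header does not match it.
    """
    if dialect not in _DIALECTS:
        raise DialectError(f"unknown dialect {dialect!r}")
    header, parse, _ = _DIALECTS[dialect]
    result = ParseResult()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            first = next(reader)
        except StopIteration:
            raise DialectError(f"{path}: empty file, expected dialect {dialect} header")
        if tuple(first) != header:
            raise DialectError(f"{path}: header does not match dialect {dialect}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            if len(row) != len(header):
                result.skipped.append(SkippedRow(lineno, "wrong column count"))
                continue
            try:
                fields = parse(row)
            except (ValueError, IndexError) as exc:
                result.skipped.append(SkippedRow(lineno, f"malformed field: {exc}"))
                continue
            g5 = canonical_gene(fields["gene5"])
            g3 = canonical_gene(fields["gene3"])
            if g5 is None or g3 is None:
                result.skipped.append(SkippedRow(lineno, "unparseable gene pair"))
                continue
            c5 = normalize_chrom(fields["chrom5"])
            c3 = normalize_chrom(fields["chrom3"])
            if c5 is None or c3 is None:
                result.skipped.append(SkippedRow(lineno, "non-canonical contig"))
                continue
            fields.update(gene5=g5, gene3=g3, chrom5=c5, chrom3=c3)
            try:
                result.calls.append(FusionCall(sample_id=sample_id, caller=dialect, **fields))
            except ValueError as exc:
                result.skipped.append(SkippedRow(lineno, str(exc)))
    return result


def write_caller_table(calls: Iterable[FusionCall], path, dialect: str) -> None:
    """Write calls in one caller's native dialect (fixture/simulation output)."""
    if dialect not in _DIALECTS:
        raise DialectError(f"unknown dialect {dialect!r}")
    header, _, fmt = _DIALECTS[dialect]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for call in sorted(calls, key=FusionCall.sort_key):
            writer.writerow(fmt(call))


def write_fusion_table(calls: Iterable[FusionCall], path) -> None:
    """Write the normalized fusion table (TSV, fixed columns, sorted rows).

    Row order is deterministic — (sample_id, gene5, gene3, pos5, pos3,
    caller) — so identical call sets produce identical bytes.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(NORMALIZED_COLUMNS)
        for c in sorted(calls, key=FusionCall.sort_key):
            writer.writerow([
                c.sample_id, c.caller,
                c.gene5, c.chrom5, c.pos5, c.strand5,
                c.gene3, c.chrom3, c.pos3, c.strand3,
                c.split_reads, c.discordant_pairs,
                "true" if c.read_through else "false",
            ])


def read_fusion_table(path) -> ParseResult:
    """Read a normalized fusion table written by :func:`write_fusion_table`."""
    result = ParseResult()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise DialectError(f"{path}: empty file, expected normalized header")
        if tuple(header) != NORMALIZED_COLUMNS:
            raise DialectError(f"{path}: not a normalized fusion table")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            try:
                result.calls.append(FusionCall(
                    sample_id=row[0], caller=row[1],
                    gene5=row[2], chrom5=row[3], pos5=int(row[4]), strand5=row[5],
                    gene3=row[6], chrom3=row[7], pos3=int(row[8]), strand3=row[9],
                    split_reads=int(row[10]), discordant_pairs=int(row[11]),
                    read_through=row[12].strip().lower() == "true",
                ))
            except (ValueError, IndexError) as exc:
                result.skipped.append(SkippedRow(lineno, str(exc)))
    return result


def load_gene_pair_list(path, mode: str, name: str | None = None) -> GenePairList:
    """Load a headerless TSV gene-pair (2 columns) or single-gene (1) list.

    Duplicate rows deduplicate; a row with the wrong column count for the
    requested mode raises ``ValueError``.
    """
    if mode not in ("pairs", "genes"):
        raise ValueError(f"mode must be 'pairs' or 'genes', got {mode!r}")
    want = 2 if mode == "pairs" else 1
    pairs: set[tuple[str, str]] = set()
    genes: set[str] = set()
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or all(not f.strip() for f in row):
                continue
            if len(row) != want:
                raise ValueError(f"{path}:{lineno}: expected {want} columns for mode {mode!r}")
            symbols = [s.strip() for s in row]
            if any(not s for s in symbols):
                raise ValueError(f"{path}:{lineno}: empty symbol")
            if mode == "pairs":
                pairs.add((symbols[0], symbols[1]))
            else:
                genes.add(symbols[0])
    return GenePairList(name=name or Path(path).stem,
                        pairs=frozenset(pairs), single_genes=frozenset(genes))


def write_gene_pair_list(gpl: GenePairList, path, mode: str) -> None:
    """Write a gene-pair or single-gene list back to headerless TSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if mode == "pairs":
            for g5, g3 in sorted(gpl.pairs):
                writer.writerow([g5, g3])
        elif mode == "genes":
            for g in sorted(gpl.single_genes):
                writer.writerow([g])
        else:
            raise ValueError(f"mode must be 'pairs' or 'genes', got {mode!r}")
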