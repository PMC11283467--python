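"""Single-sample rank-based immune enrichment scoring.

For each sample, genes are ranked by expression (average ranks on ties) and
the enrichment score of a gene set is the summed difference between the
rank-weighted in-set empirical CDF (weights = rank^alpha) and the unweighted
out-of-set ECDF, walking genes from highest to lowest expression — the
ssGSEA statistic.  Scores are rank-based and therefore invariant to any
strictly increasing per-sample transform of the expression values; they are
comparable within a cohort only, which the 60th-percentile grouping respects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .burden_survival import dichotomize_quantile


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene set is empty")


def load_gene_set(path, name: str | None = None) -> GeneSet:
    """Read a gene set: one symbol per line."""
    with open(path) as fh:
        genes = frozenset(line.strip() for line in fh if line.strip())
    return GeneSet(name=name or str(path), genes=genes)


def load_expression(path, sep: str | None = None) -> pd.DataFrame:
    """Read a genes x samples expression matrix (first column = gene symbol)."""
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        raise ValueError("duplicate gene symbols in expression matrix")
    return df


def ssgsea_score(expr: pd.DataFrame, gene_set: GeneSet,
                 alpha: float = 0.25) -> pd.Series:
    """Per-sample single-sample enrichment score of ``gene_set``.

    ``expr`` is genes x samples (non-negative TPM).  At least two set genes
    must be present in the matrix.  With ``alpha=0`` the statistic reduces to
    an unweighted two-sample rank comparison between in-set and out-of-set
    genes.  Tied expression values receive average ranks; the walk order
    breaks rank ties by gene symbol, so scores do not depend on the row order
    of the input matrix.
    """
    if expr.index.has_duplicates:
        raise ValueError("duplicate gene symbols in expression matrix")
    genes = expr.index.to_numpy()
    in_set = np.isin(genes, list(gene_set.genes))
    m = int(in_set.sum())
    n_genes = len(genes)
    if m < 2:
        raise ValueError(f"gene set {gene_set.name!r}: fewer than 2 genes "
                         "overlap the expression matrix")
    if m >= n_genes:
        raise ValueError("gene set covers the whole matrix; no out-of-set genes")
    # deterministic symbol-based tie-break for the walk order
    symbol_order = np.argsort(np.argsort(genes))
    values = expr.to_numpy(dtype=float)

    scores = {}
    for j, sample in enumerate(expr.columns):
        ranks = rankdata(values[:, j])  # average ranks, 1..N (high expr = high rank)
        order = np.lexsort((symbol_order, -ranks))
        mask = in_set[order]
        w = np.where(mask, ranks[order] ** alpha, 0.0)
        p_in = np.cumsum(w) / w.sum()
        p_out = np.cumsum(~mask) / (n_genes - m)
        scores[sample] = float(np.sum(p_in - p_out))
    return pd.Series(scores, name=f"ssgsea:{gene_set.name}")


def immune_groups(scores: Mapping[str, float], q: float = 0.6) -> dict[str, str]:
    """High/low immune-score groups at the empirical q-quantile (strict >)."""
    groups, _ = dichotomize_quantile(dict(scores), q)
    return groups
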