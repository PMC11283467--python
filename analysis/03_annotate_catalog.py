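#!/usr/bin/env python
"""Build the cohort-level fusion catalog and its summary tables.

Collapses consensus events to unique ordered gene pairs, annotates them
against the known-fusion database, cross-tabulates private/recurrent x
unknown/known, tallies the per-chromosome inter/intra distribution under the
counted-twice convention, and summarizes burden by subtype.
"""

import argparse
from pathlib import Path

import pandas as pd

from fusionburden.caller_io import load_gene_pair_list
from fusionburden.fusion_annotate import (build_catalog, burden_by_group,
                                          chromosome_table,
                                          classification_table)
from fusionburden.fusion_filter import read_consensus_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    bundle = args.outdir / "cohort"

    fusions = read_consensus_table(args.outdir / "consensus_fusions.tsv")
    known = [load_gene_pair_list(bundle / "known_fusions.tsv", "pairs")]
    catalog = build_catalog(fusions, known)
    catalog.to_frame().to_csv(args.outdir / "fusion_catalog.tsv", sep="\t", index=False)
    print(f"{len(catalog)} unique fusions from {len(fusions)} per-sample events\n")

    table = classification_table(catalog)
    print(table.to_text(), "\n")
    table.counts.to_csv(args.outdir / "classification_counts.tsv", sep="\t")
    table.percentages.to_csv(args.outdir / "classification_pct.tsv", sep="\t")

    chrom = chromosome_table(catalog)
    chrom.to_csv(args.outdir / "chromosome_table.tsv", sep="\t", index_label="chrom")
    top = chrom.assign(total=chrom["inter"] + chrom["intra"]).nlargest(3, "total")
    print("chromosomes with the most fusions (counted twice):")
    print(top[["inter", "intra", "intra_pct"]].to_string(), "\n")

    clinical = pd.read_csv(bundle / "clinical.csv")
    burden = pd.read_csv(args.outdir / "fusion_burden.tsv", sep="\t",
                         index_col="sample_id")["burden"].to_dict()
    by_intrinsic = burden_by_group(burden, dict(zip(clinical["sample_id"],
                                                    clinical["intrinsic"])))
    by_intrinsic.to_csv(args.outdir / "burden_by_intrinsic.tsv", sep="\t")
    print("fusion burden by intrinsic subtype:")
    print(by_intrinsic.to_string())


if __name__ == "__main__":
    main()
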