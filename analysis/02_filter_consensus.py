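#!/usr/bin/env python
"""Harmonize caller output and apply the filter cascade.

Reads every per-sample caller file from the simulated bundle, applies the
support filter (>=3 total reads, >=1 split read), the read-through filter,
the blacklist filter and the 2-of-3 caller consensus, and writes the
surviving consensus events plus the per-sample fusion burden.
"""

import argparse
import statistics
from collections import Counter
from pathlib import Path

import pandas as pd

from fusionburden.caller_io import load_gene_pair_list
from fusionburden.fusion_filter import (FilterConfig, consensus_merge,
                                        filter_blacklist, filter_read_through,
                                        filter_support, per_sample_burden,
                                        write_consensus_table)
from fusionburden.synthetic_cohort import read_bundle_calls


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    bundle = args.outdir / "cohort"

    calls, skipped = read_bundle_calls(bundle)
    blacklists = [load_gene_pair_list(bundle / "blacklist_pairs.tsv", "pairs"),
                  load_gene_pair_list(bundle / "blacklist_genes.tsv", "genes")]
    cfg = FilterConfig()

    per_caller = Counter(c.caller for c in calls)
    med = {caller: statistics.median(
        Counter(c.sample_id for c in calls if c.caller == caller).values())
        for caller in per_caller}
    print(f"read {len(calls)} calls ({skipped} rows skipped); "
          f"median raw calls per sample by caller: {dict(sorted(med.items()))}")

    stage = filter_support(calls, cfg)
    print(f"support filter:      {len(calls) - len(stage):5d} removed, {len(stage)} kept")
    n = len(stage)
    stage = filter_read_through(stage, cfg)
    print(f"read-through filter: {n - len(stage):5d} removed, {len(stage)} kept")
    n = len(stage)
    stage = filter_blacklist(stage, blacklists)
    print(f"blacklist filter:    {n - len(stage):5d} removed, {len(stage)} kept")
    fusions = consensus_merge(stage, cfg)
    print(f"2-of-3 consensus:    {len(fusions)} per-sample events")

    clinical = pd.read_csv(bundle / "clinical.csv")
    burden = per_sample_burden(fusions, list(clinical["sample_id"].astype(str)))
    write_consensus_table(fusions, args.outdir / "consensus_fusions.tsv")
    pd.Series(burden, name="burden").rename_axis("sample_id").to_csv(
        args.outdir / "fusion_burden.tsv", sep="\t")
    print(f"median fusion burden after filtering: "
          f"{statistics.median(burden.values())}")


if __name__ == "__main__":
    main()
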