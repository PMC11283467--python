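"""Filter cascade and 2-of-3 caller consensus."""

import dataclasses
import itertools

import pytest

from fusionburden.caller_io import GenePairList
from fusionburden.fusion_filter import (ConsensusFusion, FilterConfig,
                                        consensus_merge, filter_blacklist,
                                        filter_read_through, filter_support,
                                        per_sample_burden, run_filter_pipeline)
from helpers import brute_keep, brute_pipeline, consensus_to_dict, random_calls
from test_caller_io import make_call

CFG = FilterConfig()


class TestSupportFilter:
    def test_no_split_reads_removed(self):
        """A call with discordant pairs only fails the split-read rule."""
        assert filter_support([make_call(split_reads=0, discordant_pairs=5)], CFG) == []

    def test_three_total_reads_kept(self):
        """Exactly three supporting reads (all split) pass the >=3 rule."""
        call = make_call(split_reads=3, discordant_pairs=0)
        assert filter_support([call], CFG) == [call]

    def test_matches_brute_force_on_random_calls(self, rng):
        calls = random_calls(rng, 200)
        kept = filter_support(calls, CFG)
        expected = [c for c in calls
                    if c.total_support >= 3 and c.split_reads >= 1]
        assert kept == expected


class TestReadThroughFilter:
    def test_flagged_call_removed(self):
        assert filter_read_through([make_call(read_through=True)], CFG) == []

    def test_interchromosomal_unflagged_kept(self):
        call = make_call(chrom5="chr1", chrom3="chr2")
        assert filter_read_through([call], CFG) == [call]

    def test_planted_read_throughs_exactly_removed(self, rng):
        """100 calls with 12 planted read-throughs: exactly those 12 go."""
        clean = []
        while len(clean) < 88:
            c = random_calls(rng, 1, flagged_frac=0.0)[0]
            near = (c.chrom5 == c.chrom3 and c.strand5 == c.strand3
                    and 0 < c.pos3 - c.pos5 <= CFG.read_through_max_gap)
            if not near:
                clean.append(c)
        planted = []
        for i in range(12):
            if i % 2 == 0:
                planted.append(make_call(read_through=True, pos5=1000 + i))
            else:
                planted.append(make_call(chrom5="chr3", chrom3="chr3", strand5="+",
                                         strand3="+", pos5=10_000, pos3=10_000 + 100 * i))
        kept = filter_read_through(clean + planted, CFG)
        assert kept == clean

    def test_gap_boundary_is_inclusive(self):
        at_gap = make_call(chrom5="chr1", chrom3="chr1", strand5="+", strand3="+",
                           pos5=1, pos3=1 + CFG.read_through_max_gap)
        past_gap = dataclasses.replace(at_gap, pos3=2 + CFG.read_through_max_gap)
        assert filter_read_through([at_gap, past_gap], CFG) == [past_gap]


class TestBlacklistFilter:
    BL = [GenePairList("bl1", pairs=frozenset({("FBXL20", "BCAS3")})),
          GenePairList("bl2", single_genes=frozenset({"NTRK1"}))]

    def test_listed_pair_removed(self):
        assert filter_blacklist([make_call()], self.BL) == []

    def test_single_gene_ban_hits_either_partner(self):
        call = make_call(gene5="ESR1", gene3="NTRK1")
        assert filter_blacklist([call], self.BL) == []

    def test_empty_blacklists_identity(self, rng):
        calls = random_calls(rng, 50)
        assert filter_blacklist(calls, []) == calls

    def test_matches_set_membership_scan(self, rng):
        calls = random_calls(rng, 200)
        kept = filter_blacklist(calls, self.BL)
        expected = [c for c in calls
                    if (c.gene5, c.gene3) not in self.BL[0].pairs
                    and c.gene5 != "NTRK1" and c.gene3 != "NTRK1"]
        assert kept == expected


class TestConsensus:
    def test_two_caller_pair_kept(self):
        calls = [make_call(caller="A"), make_call(caller="B", split_reads=9)]
        (fusion,) = consensus_merge(calls, CFG)
        assert fusion.callers == frozenset({"A", "B"})
        assert fusion.split_reads == 9          # per-field max across callers
        assert fusion.total_support == 11

    def test_single_caller_pair_dropped(self):
        assert consensus_merge([make_call(caller="C")], CFG) == []

    def test_duplicate_rows_collapse_to_max(self):
        calls = [make_call(caller="A", split_reads=3, discordant_pairs=0),
                 make_call(caller="A", split_reads=8, discordant_pairs=1),
                 make_call(caller="B")]
        (fusion,) = consensus_merge(calls, CFG)
        assert fusion.split_reads == 8 and fusion.total_support == 9

    def test_intrachromosomal_flag(self):
        calls = [make_call(caller="A"), make_call(caller="B")]
        (fusion,) = consensus_merge(calls, CFG)
        assert fusion.intrachromosomal

    @pytest.mark.parametrize("seed", range(20))
    def test_randomized_instances_match_enumeration(self, seed):
        import numpy as np
        rng = np.random.default_rng(seed)
        calls = random_calls(rng, int(rng.integers(5, 60)), n_samples=5)
        got = consensus_to_dict(consensus_merge(calls, FilterConfig(
            min_total_support=0, min_split_reads=0, read_through_max_gap=0,
            drop_flagged_read_through=False)))
        cfg0 = FilterConfig(min_total_support=0, min_split_reads=0,
                            read_through_max_gap=0, drop_flagged_read_through=False)
        assert got == brute_pipeline(calls, cfg0)


class TestCascadeProperties:
    def test_per_call_filters_commute(self, rng):
        """The three per-call filters are pure predicates: any application
        order yields the same surviving set."""
        bls = [GenePairList("bl", pairs=frozenset({("ESR1", "TP53")}),
                            single_genes=frozenset({"IKZF3"}))]
        steps = {
            "support": lambda cc: filter_support(cc, CFG),
            "rt": lambda cc: filter_read_through(cc, CFG),
            "bl": lambda cc: filter_blacklist(cc, bls),
        }
        for _ in range(100):
            calls = random_calls(rng, 30)
            results = []
            for order in itertools.permutations(steps):
                out = calls
                for name in order:
                    out = steps[name](out)
                results.append(set(out))
            assert all(r == results[0] for r in results)

    def test_identity_regime(self, rng):
        """min_callers=1, zero thresholds, no blacklists: the pipeline is the
        identity on distinct (sample, pair) events."""
        cfg = FilterConfig(min_total_support=0, min_split_reads=0, min_callers=1,
                           read_through_max_gap=0, drop_flagged_read_through=False)
        calls = random_calls(rng, 80)
        fusions = run_filter_pipeline(calls, cfg, [])
        assert {(f.sample_id, f.pair) for f in fusions} == \
            {(c.sample_id, (c.gene5, c.gene3)) for c in calls}

    def test_consensus_output_bounded_and_supported(self, rng):
        calls = random_calls(rng, 120)
        kept = filter_support(calls, CFG)
        fusions = consensus_merge(kept, CFG)
        assert len(fusions) <= len({(c.sample_id, (c.gene5, c.gene3)) for c in kept})
        for f in fusions:
            callers = {c.caller for c in kept
                       if c.sample_id == f.sample_id and (c.gene5, c.gene3) == f.pair}
            assert f.callers <= callers and len(f.callers) >= CFG.min_callers


class TestBurden:
    def _cf(self, sample, g5, g3):
        return ConsensusFusion(sample_id=sample, gene5=g5, gene3=g3,
                               chrom5="chr1", chrom3="chr2",
                               callers=frozenset({"A", "B"}),
                               split_reads=5, total_support=8)

    def test_ordered_pairs_count_separately(self):
        fusions = [self._cf("s1", "X", "Y"), self._cf("s1", "Y", "X")]
        assert per_sample_burden(fusions) == {"s1": 2}

    def test_zero_burden_samples_present(self):
        fusions = [self._cf("s1", "X", "Y")]
        assert per_sample_burden(fusions, all_samples=["s1", "s2"]) == {"s1": 1, "s2": 0}

    def test_burden_sums_to_event_count(self, rng):
        calls = random_calls(rng, 150)
        fusions = run_filter_pipeline(calls, CFG, [])
        assert sum(per_sample_burden(fusions).values()) == len(fusions)


def test_filter_config_validation():
    with pytest.raises(ValueError):
        FilterConfig(min_callers=0)
    with pytest.raises(ValueError):
        FilterConfig(min_total_support=-1)
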