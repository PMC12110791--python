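"""CNVR construction (transitive 1 bp overlap union, class, length caps)
against a per-base brute-force oracle, plus landscape summaries."""

import numpy as np
import pytest

from cnvpop.cnvr_builder import LengthPolicy, build_cnvrs, summarize_landscape
from cnvpop.io_formats import CnvCall, GenomeLayout

LAYOUT = GenomeLayout(("chrA",), (100_000,))


def call(sample, start, end, svtype="DUP", chrom="chrA"):
    return CnvCall(sample, "CONSENSUS", chrom, start, end, svtype)


NO_CAPS = LengthPolicy(10**9, 10**9, 10**9)


def per_base_oracle(calls, chrom_len=100_000):
    """Mark covered bases, extract maximal runs with their svtype sets.

    Coverage is marked at doubled resolution over [2*start, 2*end - 1) so
    that merely touching half-open intervals (end == next start, no shared
    base) stay separate while any 1 bp overlap joins runs.
    """
    covered = np.zeros(2 * chrom_len, dtype=bool)
    for c in calls:
        covered[2 * c.start : 2 * c.end - 1] = True
    edges = np.flatnonzero(np.diff(np.concatenate([[0], covered.view(np.int8), [0]])))
    regions = []
    for a, b in zip(edges[::2], edges[1::2]):
        start, end = int(a) // 2, (int(b) + 1) // 2
        types = {c.svtype for c in calls if c.start < end and c.end > start}
        regions.append((start, end, frozenset(types)))
    return regions


class TestBuild:
    def test_cross_type_cross_sample_union(self):
        calls = [call("A", 100, 500, "DUP"), call("B", 400, 900, "DEL")]
        (r,) = build_cnvrs(calls, NO_CAPS)
        assert (r.start, r.end, r.cnvr_class, r.length) == (100, 900, "both", 800)
        assert r.carriers == {"A": {"DUP"}, "B": {"DEL"}}

    def test_adjacent_half_open_intervals_stay_separate(self):
        calls = [call("A", 100, 200), call("B", 200, 300)]
        regions = build_cnvrs(calls, NO_CAPS)
        assert [(r.start, r.end) for r in regions] == [(100, 200), (200, 300)]

    @pytest.mark.parametrize(
        "svtype,length,kept",
        [
            ("DEL", 60_000, False),   # loss above 50 kb cap
            ("DEL", 50_000, True),    # "did not exceed": equal length retained
            ("DUP", 60_000, True),    # gain cap is 500 kb
            ("DUP", 600_000, False),
        ],
    )
    def test_class_specific_length_caps(self, svtype, length, kept):
        layout = GenomeLayout(("chrA",), (1_000_000,))
        calls = [call("A", 0, length, svtype)]
        regions = build_cnvrs(calls, LengthPolicy(), layout)
        assert bool(regions) is kept

    def test_mixed_region_above_cap_discarded(self):
        calls = [call("A", 0, 30_000, "DUP"), call("B", 20_000, 60_000, "DEL")]
        assert build_cnvrs(calls, LengthPolicy()) == []

    def test_ids_in_genomic_order_and_order_invariance(self):
        rng = np.random.default_rng(7)
        calls = [
            call(f"s{i}", int(s), int(s) + int(l))
            for i, (s, l) in enumerate(
                zip(rng.integers(0, 90_000, 25), rng.integers(500, 5_000, 25))
            )
        ]
        ref = build_cnvrs(calls, NO_CAPS)
        assert [r.cnvr_id for r in ref] == [f"cnvr_{i + 1}" for i in range(len(ref))]
        assert all(a.end <= b.start for a, b in zip(ref, ref[1:]))
        shuffled = list(calls)
        rng.shuffle(shuffled)
        assert build_cnvrs(shuffled, NO_CAPS) == ref

    def test_matches_per_base_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(1, 50))
            calls = []
            for i in range(n):
                start = int(rng.integers(0, 95_000))
                length = int(rng.integers(1, 5_000))
                svtype = "DUP" if rng.random() < 0.5 else "DEL"
                calls.append(call(f"s{i % 5}", start, start + length, svtype))
            got = [(r.start, r.end, frozenset(t for ts in r.carriers.values() for t in ts))
                   for r in build_cnvrs(calls, NO_CAPS)]
            assert got == per_base_oracle(calls)

    def test_kept_plus_discarded_partitions_raw_regions(self):
        rng = np.random.default_rng(13)
        layout = GenomeLayout(("chrA",), (10_000_000,))
        calls = []
        for i in range(60):
            start = int(rng.integers(0, 9_000_000))
            length = int(rng.integers(1_000, 120_000))
            svtype = "DUP" if rng.random() < 0.5 else "DEL"
            calls.append(call(f"s{i % 6}", start, start + length, svtype, "chrA"))
        raw = build_cnvrs(calls, None, layout)
        kept = build_cnvrs(calls, LengthPolicy(), layout)
        kept_spans = {(r.chrom, r.start, r.end) for r in kept}
        raw_spans = {(r.chrom, r.start, r.end) for r in raw}
        assert kept_spans <= raw_spans
        discarded = raw_spans - kept_spans
        assert len(kept) + len(discarded) == len(raw)
        assert any(discarded), "instance should exercise the caps"


class TestSummary:
    def test_arithmetic_on_known_lengths(self):
        layout = GenomeLayout(("chrA",), (1_000_000,))
        cnvrs = build_cnvrs(
            [call("A", 0, 1000), call("A", 10_000, 13_000, "DEL"), call("A", 50_000, 58_000)],
            NO_CAPS, layout,
        )
        s = summarize_landscape(cnvrs, layout)
        assert s.n_total == 3 and s.n_gain == 2 and s.n_loss == 1 and s.n_both == 0
        assert s.total_len == 12_000
        assert s.genome_fraction == pytest.approx(0.012)
        assert list(s.size_class_counts.values()) == [1, 1, 1, 0]

    def test_mean_length_reported_as_floor(self):
        layout = GenomeLayout(("chrA",), (1_000_000,))
        cnvrs = build_cnvrs([call("A", 0, 1001), call("A", 5_000, 7_000)], NO_CAPS, layout)
        s = summarize_landscape(cnvrs, layout)
        assert s.mean_len_exact == pytest.approx(1500.5)
        assert s.mean_len == 1500

    def test_bin_boundary_is_half_open(self):
        layout = GenomeLayout(("chrA",), (1_000_000,))
        cnvrs = build_cnvrs([call("A", 0, 2000)], NO_CAPS, layout)
        s = summarize_landscape(cnvrs, layout)
        assert s.size_class_counts["[2000,5000)"] == 1
        assert s.size_class_counts["[0,2000)"] == 0

    def test_empty_input_flagged(self):
        s = summarize_landscape([], LAYOUT)
        assert s.empty and s.n_total == 0 and s.mean_len == 0

    def test_counts_sum_and_bins_partition(self, default_products):
        layout = default_products.cohort.layout
        s = summarize_landscape(default_products.cnvrs, layout)
        assert s.n_total == s.n_gain + s.n_loss + s.n_both
        assert sum(s.size_class_counts.values()) == s.n_total
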