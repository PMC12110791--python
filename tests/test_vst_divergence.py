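"""Vst arithmetic against hand-computed and brute-force oracles, its
invariances, outlier calling and outlier-gene listing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cnvpop.annotation_overlap import ContextCall
from cnvpop.genotyping import CnMatrix
from cnvpop.io_formats import DataError, PopulationMap
from cnvpop.vst_divergence import (
    OutlierPolicy,
    call_outliers,
    mean_vst,
    outlier_genes,
    vst_pairwise,
)


def matrix_from(rows, samples):
    values = pd.DataFrame(rows, index=[f"r{i}" for i in range(len(rows))], columns=samples)
    mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    return CnMatrix(values=values, mask=mask)


def two_pop_setup(values_a, values_b):
    samples = [f"a{i}" for i in range(len(values_a))] + [f"b{i}" for i in range(len(values_b))]
    pops = PopulationMap({s: ("A" if s.startswith("a") else "B") for s in samples})
    return matrix_from([list(values_a) + list(values_b)], samples), pops


def brute_force_vst(values_a, values_b):
    """Two-pass divisor-n variance computation, independent of the library."""
    def var(xs):
        mean = sum(xs) / len(xs)
        return sum((x - mean) ** 2 for x in xs) / len(xs)

    pooled = list(values_a) + list(values_b)
    vt = var(pooled)
    if vt == 0:
        return 0.0
    vs = (len(values_a) * var(values_a) + len(values_b) * var(values_b)) / len(pooled)
    return (vt - vs) / vt


class TestVstArithmetic:
    def test_fixed_between_population_difference_gives_one(self):
        m, pops = two_pop_setup([2, 2, 2], [4, 4, 4])
        (r,) = vst_pairwise(m, pops, ("A", "B"))
        assert r.vst == 1.0 and r.vs == 0.0 and r.vt == 1.0

    def test_invariant_region_gives_zero(self):
        m, pops = two_pop_setup([2, 2, 2], [2, 2, 2])
        (r,) = vst_pairwise(m, pops, ("A", "B"))
        assert r.vt == 0.0 and r.vst == 0.0

    def test_hand_computed_case(self):
        m, pops = two_pop_setup([2, 2, 3], [4, 4, 5])
        (r,) = vst_pairwise(m, pops, ("A", "B"))
        assert r.vt == pytest.approx(11 / 9)
        assert r.vs == pytest.approx(2 / 9)
        assert r.vst == pytest.approx(9 / 11)  # 0.8182

    def test_pair_label_order_irrelevant(self):
        m, pops = two_pop_setup([2, 3, 2], [4, 5, 4])
        (ab,) = vst_pairwise(m, pops, ("A", "B"))
        (ba,) = vst_pairwise(m, pops, ("B", "A"))
        assert ab == ba

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(3)
        va, vb = rng.uniform(0, 6, 5), rng.uniform(0, 6, 7)
        base = brute_force_vst(list(va), list(vb))
        assert brute_force_vst(list(va + 3), list(vb + 3)) == pytest.approx(base, abs=1e-12)
        m, pops = two_pop_setup(list(va * 2.5), list(vb * 2.5))
        (r,) = vst_pairwise(m, pops, ("A", "B"))
        assert r.vst == pytest.approx(base, abs=1e-12)

    def test_small_population_rejected(self):
        m, pops = two_pop_setup([2], [4, 4])
        with pytest.raises(DataError, match=">= 2"):
            vst_pairwise(m, pops, ("A", "B"))

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n1, n2 = int(rng.integers(2, 11)), int(rng.integers(2, 11))
            n_regions = int(rng.integers(1, 51))
            samples = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
            pops = PopulationMap({s: ("A" if s.startswith("a") else "B") for s in samples})
            rows = rng.uniform(0, 8, (n_regions, n1 + n2))
            m = matrix_from(rows.tolist(), samples)
            records = vst_pairwise(m, pops, ("A", "B"))
            for i, r in enumerate(records):
                expected = brute_force_vst(list(rows[i, :n1]), list(rows[i, n1:]))
                assert abs(r.vst - expected) < 1e-12


@settings(max_examples=50, derandomize=True)
@given(
    va=st.lists(st.floats(0, 10, allow_nan=False), min_size=2, max_size=8),
    vb=st.lists(st.floats(0, 10, allow_nan=False), min_size=2, max_size=8),
)
def test_vst_never_exceeds_one_and_zero_vt_convention(va, vb):
    m, pops = two_pop_setup(va, vb)
    (r,) = vst_pairwise(m, pops, ("A", "B"))
    assert r.vst <= 1.0
    if r.vt == 0:
        assert r.vst == 0.0


class TestMeanAndOutliers:
    def _records(self, values):
        samples = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
        pops = PopulationMap({s: ("A" if s.startswith("a") else "B") for s in samples})
        # craft rows whose vst is 1 (diverged) or 0 (invariant) as requested
        rows = [[2, 2, 2, 4, 4, 4] if v == 1.0 else [2, 2, 2, 2, 2, 2] for v in values]
        return vst_pairwise(matrix_from(rows, samples), pops, ("A", "B"))

    def test_mean_of_extremes(self):
        records = self._records([1.0, 0.0])
        assert mean_vst(records) == pytest.approx(0.5)
        assert mean_vst(records[:1]) == 1.0
        with pytest.raises(DataError):
            mean_vst([])

    def test_top_fraction_count(self):
        rng = np.random.default_rng(9)
        samples = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
        pops = PopulationMap({s: ("A" if s.startswith("a") else "B") for s in samples})
        rows = rng.uniform(0, 6, (100, 6)).tolist()
        records = vst_pairwise(matrix_from(rows, samples), pops, ("A", "B"))
        ids, threshold = call_outliers(records, OutlierPolicy(top_fraction=0.05))
        assert len(ids) == 5
        chosen = {r.cnvr_id: r.vst for r in records if r.cnvr_id in set(ids)}
        assert min(chosen.values()) == threshold
        assert all(r.vst <= threshold for r in records if r.cnvr_id not in chosen)

    def test_percentile_mode_degenerate_distribution(self):
        records = self._records([0.0] * 10)
        ids, threshold = call_outliers(
            records, OutlierPolicy(mode="percentile_threshold", percentile=98)
        )
        assert ids == [] and threshold == 0.0

    def test_percentile_mode_strictly_above(self):
        records = self._records([1.0] * 2 + [0.0] * 98)
        ids, threshold = call_outliers(
            records, OutlierPolicy(mode="percentile_threshold", percentile=98)
        )
        assert set(ids) == {r.cnvr_id for r in records if r.vst == 1.0}

    def test_percentile_rank_spans_records(self):
        records = self._records([1.0, 0.0, 0.0])
        by_vst = sorted(records, key=lambda r: r.vst)
        assert by_vst[-1].percentile_rank == pytest.approx(100.0)
        assert all(0 < r.percentile_rank <= 100 for r in records)


class TestOutlierGenes:
    CONTEXTS = [
        ContextCall("c1", "exonic", {"gA", "gB"}),
        ContextCall("c2", "intergenic", set()),
        ContextCall("c3", "intronic", {"gB", "gC"}),
    ]

    def test_union_deduplicated_sorted(self):
        assert outlier_genes(["c1", "c3"], self.CONTEXTS) == ["gA", "gB", "gC"]

    def test_gene_free_outlier_contributes_nothing(self):
        assert outlier_genes(["c2"], self.CONTEXTS) == []
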