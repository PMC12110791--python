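"""Synthetic multi-population CNV cohort with known ground truth.

The generator emulates the downstream products of a three-population
cattle resequencing cohort: per-sample, per-caller CNV call files over a
miniature genome, windowed depth tracks consistent with each sample's true
copy numbers, a gene annotation, a QTL table and a population map.  Its
defaults mirror the study conditions the pipeline is designed for — three
populations of 7/10/10 samples, a genome of 3 chromosomes x 10 Mb, 60
shared and 12 population-divergent CNV loci, 50 bp breakpoint jitter, 5%
caller false negatives, 2% false positives and 30 reads per 1 kb window.

True loci are placed on window boundaries (read-depth callers resolve
breakpoints at bin resolution anyway), are at least 2 kb long so that
truth survives the >1 kb call-length filter even after jitter, and carry
integer true copy numbers: deletions are heterozygous (CN 1) or homozygous
(CN 0), duplications CN 3-6.  Divergent loci contrast one target
population pair — the first population fixed diploid, the second fixed at
the shifted copy number (so the pair's expected Vst is exactly 1) — while
the third population is a 50/50 mixture, giving the non-target pairs
intermediate divergence.  Expected Vst values are computed exactly from
the assigned copy numbers, not estimated.

Every random draw flows from a single integer-seeded NumPy generator, so
one seed fixes the cohort byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .cnvr_builder import Cnvr
from .genotyping import CnMatrix, DepthTrack, write_depth_track
from .io_formats import (
    CALLER_ROLES,
    CnvCall,
    DataError,
    GeneModel,
    GenomeLayout,
    PopulationMap,
    QtlRecord,
    write_calls,
    write_genome_layout,
    write_gff3,
    write_population_map,
    write_qtl_table,
)

__all__ = [
    "SimConfig",
    "TrueLocus",
    "SimulatedCohort",
    "simulate_cohort",
    "truth_report",
    "read_truth_report",
    "true_cn_matrix",
    "match_loci_to_cnvrs",
    "write_cohort",
]

_TRAIT_NAMES = (
    "Subcutaneous fat thickness",
    "Longissimus muscle area",
    "Multiple birth",
    "Tenderness score",
    "Antral follicle number",
    "Body weight",
    "Marbling score",
    "Meat color",
)


def _default_genome() -> GenomeLayout:
    return GenomeLayout(("chr1", "chr2", "chr3"), (10_000_000, 10_000_000, 10_000_000))


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    genome: GenomeLayout = field(default_factory=_default_genome)
    populations: tuple[tuple[str, int], ...] = (("NY", 7), ("PN", 10), ("XN", 10))
    n_shared_loci: int = 60
    n_divergent_loci: int = 12
    locus_length_range: tuple[int, int] = (2_000, 20_000)  # log-uniform, bp
    carrier_freq_range: tuple[float, float] = (0.3, 0.8)
    jitter_sd: float = 50.0
    fn_rate: float = 0.05
    fp_rate: float = 0.02
    depth_mean: float = 30.0
    window_size: int = 1_000
    depth_noise: bool = True
    dup_cn_range: tuple[int, int] = (3, 6)
    del_homozygous_prob: float = 0.2
    min_locus_gap: int = 5_000
    n_genes: int = 90
    n_qtls: int = 30
    n_wide_qtls: int = 3  # QTLs spanning >= 5 Mb, removed by the span filter

    def __post_init__(self) -> None:
        lo, hi = self.carrier_freq_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise DataError("carrier_freq_range must lie within [0, 1]")
        if self.locus_length_range[0] < 1_000:
            raise DataError("locus lengths must be >= 1 kb to survive the call-length filter")
        for name in ("fn_rate", "fp_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name} must be in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{pop}_{i + 1:02d}" for pop, n in self.populations for i in range(n)
        ]

    @property
    def population_map(self) -> PopulationMap:
        return PopulationMap(
            {f"{pop}_{i + 1:02d}": pop for pop, n in self.populations for i in range(n)}
        )

    @property
    def pop_pairs(self) -> list[tuple[str, str]]:
        labels = sorted(p for p, _ in self.populations)
        return [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]


@dataclass
class TrueLocus:
    locus_id: str
    chrom: str
    start: int
    end: int
    svtype: str
    cn: dict[str, int]  # per-sample true copy number (2 = non-carrier)
    divergent: bool
    target_pair: tuple[str, str] | None
    expected_vst: dict[tuple[str, str], float]

    @property
    def length(self) -> int:
        return self.end - self.start

    def carriers(self) -> list[str]:
        return [s for s, cn in self.cn.items() if cn != 2]


@dataclass
class SimulatedCohort:
    config: SimConfig
    truth: list[TrueLocus]
    calls: dict[str, dict[str, list[CnvCall]]]  # sample -> caller -> calls
    depth: dict[str, DepthTrack]
    genes: list[GeneModel]
    qtls: list[QtlRecord]
    pop_map: PopulationMap

    @property
    def layout(self) -> GenomeLayout:
        return self.config.genome


# ---------------------------------------------------------------------------
# Vst from assigned copy numbers (exact arithmetic on the generating values;
# the analysis module is tested *against* these numbers, so this helper is
# deliberately self-contained).

def _vst_of(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    pooled = np.asarray(list(values_a) + list(values_b), dtype=float)
    vt = pooled.var(ddof=0)
    if vt == 0:
        return 0.0
    n1, n2 = len(values_a), len(values_b)
    v1 = np.asarray(values_a, dtype=float).var(ddof=0)
    v2 = np.asarray(values_b, dtype=float).var(ddof=0)
    vs = (n1 * v1 + n2 * v2) / (n1 + n2)
    return float((vt - vs) / vt)


def _expected_vst(cn: dict[str, int], pops: PopulationMap, pairs) -> dict:
    out = {}
    for a, b in pairs:
        va = [cn[s] for s in pops.samples_in(a)]
        vb = [cn[s] for s in pops.samples_in(b)]
        out[(a, b)] = _vst_of(va, vb)
    return out


# ---------------------------------------------------------------------------
# Placement helpers

class _Occupancy:
    """Per-chromosome occupied intervals with a minimum-gap constraint."""

    def __init__(self) -> None:
        self.by_chrom: dict[str, list[tuple[int, int]]] = {}

    def free(self, chrom: str, start: int, end: int, gap: int) -> bool:
        for (s, e) in self.by_chrom.get(chrom, []):
            if start < e + gap and s < end + gap:
                return False
        return True

    def add(self, chrom: str, start: int, end: int) -> None:
        self.by_chrom.setdefault(chrom, []).append((start, end))


def _draw_length(rng: np.random.Generator, config: SimConfig) -> int:
    lo, hi = config.locus_length_range
    length = math.exp(rng.uniform(math.log(lo), math.log(hi)))
    w = config.window_size
    return max(2 * w, int(math.ceil(length / w)) * w)


def _place_interval(
    rng: np.random.Generator,
    config: SimConfig,
    occ: _Occupancy,
    length: int,
    gap: int,
    align: bool = True,
    max_tries: int = 2_000,
) -> tuple[str, int, int]:
    genome = config.genome
    weights = np.asarray(genome.chrom_lengths, dtype=float)
    weights /= weights.sum()
    for _ in range(max_tries):
        chrom = str(rng.choice(np.asarray(genome.chrom_names, dtype=object), p=weights))
        chrom_len = genome.lengths[chrom]
        if chrom_len <= length:
            continue
        start = int(rng.integers(0, chrom_len - length))
        if align:
            start = (start // config.window_size) * config.window_size
        end = start + length
        if occ.free(chrom, start, end, gap):
            occ.add(chrom, start, end)
            return chrom, start, end
    raise DataError(
        "could not place all simulated features; the genome is too small for the "
        "requested locus/gene/QTL load — increase chromosome lengths or reduce counts"
    )


# ---------------------------------------------------------------------------
# Cohort simulation

def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate truth loci, noisy per-caller calls, depth tracks and annotation."""
    rng = np.random.default_rng(config.seed)
    pops = config.population_map
    samples = config.sample_ids
    pairs = config.pop_pairs

    occ = _Occupancy()
    truth: list[TrueLocus] = []

    # --- divergent loci: cycle the target pair, alternate DUP/DEL
    for i in range(config.n_divergent_loci):
        target = pairs[i % len(pairs)] if pairs else None
        svtype = "DUP" if i % 2 == 0 else "DEL"
        shifted = 4 if svtype == "DUP" else 1
        length = _draw_length(rng, config)
        chrom, start, end = _place_interval(rng, config, occ, length, config.min_locus_gap)
        cn: dict[str, int] = {}
        for s in samples:
            pop = pops[s]
            if target is None:
                cn[s] = 2
            elif pop == target[0]:
                cn[s] = 2
            elif pop == target[1]:
                cn[s] = shifted
            else:
                cn[s] = shifted if rng.random() < 0.5 else 2
        truth.append(
            TrueLocus(
                locus_id=f"locus_div_{i + 1:03d}",
                chrom=chrom, start=start, end=end, svtype=svtype, cn=cn,
                divergent=True, target_pair=target,
                expected_vst=_expected_vst(cn, pops, pairs),
            )
        )

    # --- shared loci: one cohort-wide carrier frequency, CN drawn per carrier
    f_lo, f_hi = config.carrier_freq_range
    for i in range(config.n_shared_loci):
        svtype = "DUP" if rng.random() < 0.55 else "DEL"
        length = _draw_length(rng, config)
        chrom, start, end = _place_interval(rng, config, occ, length, config.min_locus_gap)
        freq = rng.uniform(f_lo, f_hi)
        while True:
            carrier_mask = rng.random(len(samples)) < freq
            if carrier_mask.sum() >= 1:
                break
        cn = {}
        for s, is_carrier in zip(samples, carrier_mask):
            if not is_carrier:
                cn[s] = 2
            elif svtype == "DUP":
                cn[s] = int(rng.integers(config.dup_cn_range[0], config.dup_cn_range[1] + 1))
            else:
                cn[s] = 0 if rng.random() < config.del_homozygous_prob else 1
        truth.append(
            TrueLocus(
                locus_id=f"locus_shr_{i + 1:03d}",
                chrom=chrom, start=start, end=end, svtype=svtype, cn=cn,
                divergent=False, target_pair=None,
                expected_vst=_expected_vst(cn, pops, pairs),
            )
        )

    truth.sort(key=lambda t: (t.chrom, t.start))

    # --- per-sample, per-caller call sets
    calls: dict[str, dict[str, list[CnvCall]]] = {}
    genome = config.genome
    for sample in samples:
        calls[sample] = {caller: [] for caller in CALLER_ROLES}
        for caller in CALLER_ROLES:
            caller_calls = calls[sample][caller]
            for locus in truth:
                if locus.cn[sample] == 2:
                    continue
                if config.fn_rate > 0 and rng.random() < config.fn_rate:
                    continue
                start, end = locus.start, locus.end
                if config.jitter_sd > 0:
                    start += int(round(rng.normal(0.0, config.jitter_sd)))
                    end += int(round(rng.normal(0.0, config.jitter_sd)))
                chrom_len = genome.lengths[locus.chrom]
                start = max(0, min(start, chrom_len - 2))
                end = max(start + 2, min(end, chrom_len))
                caller_calls.append(
                    _make_call(rng, sample, caller, locus.chrom, start, end,
                               locus.svtype, locus.cn[sample])
                )
            # false-positive decoys, placed clear of true loci so they can
            # only survive if two callers coincide (which random placement
            # makes vanishingly unlikely)
            n_fp = int(rng.binomial(len(truth), config.fp_rate)) if config.fp_rate > 0 else 0
            for _ in range(n_fp):
                length = _draw_length(rng, config)
                try:
                    fp_occ = _Occupancy()
                    fp_occ.by_chrom = {c: list(v) for c, v in occ.by_chrom.items()}
                    chrom, start, end = _place_interval(
                        rng, config, fp_occ, length, config.min_locus_gap, align=False
                    )
                except DataError:
                    continue
                svtype = "DUP" if rng.random() < 0.5 else "DEL"
                fp_cn = 3 if svtype == "DUP" else 1
                caller_calls.append(
                    _make_call(rng, sample, caller, chrom, start, end, svtype, fp_cn)
                )
            caller_calls.sort(key=lambda c: (c.chrom, c.start, c.end))

    # --- depth tracks consistent with true copy numbers
    depth: dict[str, DepthTrack] = {}
    w = config.window_size
    for sample in samples:
        counts: dict[str, np.ndarray] = {}
        for chrom, chrom_len in zip(genome.chrom_names, genome.chrom_lengths):
            n_win = math.ceil(chrom_len / w)
            expected = np.full(n_win, config.depth_mean, dtype=float)
            for locus in truth:
                if locus.chrom != chrom or locus.cn[sample] == 2:
                    continue
                expected[locus.start // w : locus.end // w] = (
                    config.depth_mean * locus.cn[sample] / 2.0
                )
            if config.depth_noise:
                counts[chrom] = rng.poisson(expected).astype(float)
            else:
                counts[chrom] = expected
        depth[sample] = DepthTrack(sample_id=sample, window_size=w, counts=counts)

    # --- genes: a third overlapping loci (exonic/intronic contexts), a third
    # within 1 kb of a locus, a third placed freely
    genes: list[GeneModel] = []
    gene_occ = _Occupancy()
    loci_cycle = truth if truth else []
    for i in range(config.n_genes):
        gene_len = int(rng.integers(3_000, 8_001))
        placed = None
        mode = i % 3
        if mode in (0, 1) and loci_cycle:
            locus = loci_cycle[i % len(loci_cycle)]
            chrom_len = genome.lengths[locus.chrom]
            if mode == 0:
                start = locus.start - int(rng.integers(500, 1_500))
            else:
                start = locus.end + int(rng.integers(100, 900))
            start = max(0, min(start, chrom_len - gene_len - 1))
            end = start + gene_len
            if gene_occ.free(locus.chrom, start, end, 0):
                gene_occ.add(locus.chrom, start, end)
                placed = (locus.chrom, start, end)
        if placed is None:
            try:
                placed = _place_interval(rng, config, gene_occ, gene_len, 0, align=False)
            except DataError:
                break
        chrom, start, end = placed
        n_exons = int(rng.integers(2, 4))
        exons = _draw_exons(rng, start, end, n_exons)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"GENE{i + 1:04d}", gene_name=f"G{i + 1}",
                chrom=chrom, start=start, end=end, strand=strand,
                exons=exons, biotype="protein_coding",
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))

    # --- QTLs: a few too wide to pass the span filter, half anchored on loci
    qtls: list[QtlRecord] = []
    for i in range(config.n_qtls):
        trait = _TRAIT_NAMES[i % len(_TRAIT_NAMES)]
        if i < config.n_wide_qtls:
            span = int(rng.integers(5_000_000, 8_000_001))
        elif i % 2 == 0 and truth:
            span = int(rng.integers(50_000, 1_500_001))
        else:
            span = int(rng.integers(20_000, 1_000_001))
        if i >= config.n_wide_qtls and i % 2 == 0 and truth:
            locus = truth[int(rng.integers(0, len(truth)))]
            mid = (locus.start + locus.end) // 2
            start = max(0, mid - span // 2)
        else:
            chrom_idx = int(rng.integers(0, len(genome.chrom_names)))
            chrom_name = genome.chrom_names[chrom_idx]
            start = int(rng.integers(0, max(1, genome.lengths[chrom_name] - span)))
            locus = None
        if locus is not None:
            chrom_name = locus.chrom
        chrom_len = genome.lengths[chrom_name]
        start = min(start, max(0, chrom_len - span - 1))
        end = min(start + span, chrom_len)
        qtls.append(
            QtlRecord(qtl_id=f"QTL{i + 1:04d}", trait_name=trait,
                      chrom=chrom_name, start=start, end=end)
        )

    return SimulatedCohort(
        config=config, truth=truth, calls=calls, depth=depth,
        genes=genes, qtls=qtls, pop_map=pops,
    )


def _make_call(rng, sample, caller, chrom, start, end, svtype, cn) -> CnvCall:
    if caller == "PAIRED":
        # split-read-pair callers report neither a depth p-value nor q0
        pval = q0 = est = None
    else:
        pval = float(rng.uniform(1e-8, 5e-4))
        q0 = float(rng.uniform(0.0, 0.45))
        est = float(max(0.0, cn + rng.normal(0.0, 0.2)))
    return CnvCall(sample_id=sample, caller=caller, chrom=chrom, start=start,
                   end=end, svtype=svtype, pval=pval, q0=q0, est_cn=est)


def _draw_exons(rng, start: int, end: int, n_exons: int) -> list[tuple[int, int]]:
    """Non-overlapping exons inside [start, end) from sorted random cuts."""
    span = end - start
    cuts = sorted(int(rng.integers(0, span)) for _ in range(2 * n_exons))
    exons = []
    for i in range(n_exons):
        s, e = start + cuts[2 * i], start + cuts[2 * i + 1]
        if e > s:
            exons.append((s, e))
    if not exons:
        exons = [(start, end)]
    return exons


# ---------------------------------------------------------------------------
# Truth table I/O and evaluation helpers

def _pair_label(pair: tuple[str, str]) -> str:
    return f"{pair[0]}-{pair[1]}"


def truth_report(truth: Sequence[TrueLocus], path, config: SimConfig) -> None:
    """Write the ground-truth table (coordinates, per-sample CN, expected Vst)."""
    pairs = config.pop_pairs
    samples = config.sample_ids
    with open(path, "w") as fh:
        cols = (
            ["locus_id", "chrom", "start", "end", "svtype", "divergent", "target_pair"]
            + [f"expected_vst_{_pair_label(p)}" for p in pairs]
            + [f"cn_{s}" for s in samples]
        )
        fh.write("\t".join(cols) + "\n")
        for t in truth:
            row = [
                t.locus_id, t.chrom, str(t.start), str(t.end), t.svtype,
                str(int(t.divergent)),
                _pair_label(t.target_pair) if t.target_pair else ".",
            ]
            row += [repr(t.expected_vst[p]) for p in pairs]
            row += [str(t.cn[s]) for s in samples]
            fh.write("\t".join(row) + "\n")


def read_truth_report(path, config: SimConfig) -> list[TrueLocus]:
    pairs = config.pop_pairs
    samples = config.sample_ids
    out: list[TrueLocus] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            target = f[idx["target_pair"]]
            out.append(
                TrueLocus(
                    locus_id=f[idx["locus_id"]],
                    chrom=f[idx["chrom"]],
                    start=int(f[idx["start"]]),
                    end=int(f[idx["end"]]),
                    svtype=f[idx["svtype"]],
                    cn={s: int(f[idx[f"cn_{s}"]]) for s in samples},
                    divergent=bool(int(f[idx["divergent"]])),
                    target_pair=tuple(target.split("-")) if target != "." else None,
                    expected_vst={
                        p: float(f[idx[f"expected_vst_{_pair_label(p)}"]]) for p in pairs
                    },
                )
            )
    return out


def true_cn_matrix(truth: Sequence[TrueLocus], samples: Sequence[str]) -> CnMatrix:
    """Noiseless genotyping: the CN matrix read straight off the truth table."""
    import pandas as pd

    values = pd.DataFrame(
        [[float(t.cn[s]) for s in samples] for t in truth],
        index=[t.locus_id for t in truth],
        columns=list(samples),
    )
    mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    return CnMatrix(values=values, mask=mask)


def match_loci_to_cnvrs(
    truth: Sequence[TrueLocus], cnvrs: Sequence[Cnvr]
) -> dict[str, str | None]:
    """Map each true locus to the CNVR with the largest overlap (or None)."""
    out: dict[str, str | None] = {}
    for t in truth:
        best, best_ov = None, 0
        for c in cnvrs:
            if c.chrom != t.chrom:
                continue
            ov = min(c.end, t.end) - max(c.start, t.start)
            if ov > best_ov:
                best, best_ov = c.cnvr_id, ov
        out[t.locus_id] = best
    return out


def write_cohort(cohort: SimulatedCohort, outdir) -> None:
    """Write the whole cohort as the pipeline's on-disk input layout."""
    outdir = Path(outdir)
    (outdir / "calls").mkdir(parents=True, exist_ok=True)
    (outdir / "depth").mkdir(parents=True, exist_ok=True)
    write_genome_layout(cohort.layout, outdir / "genome.tsv")
    write_population_map(cohort.pop_map, outdir / "populations.tsv")
    write_gff3(cohort.genes, outdir / "genes.gff3")
    write_qtl_table(cohort.qtls, outdir / "qtls.tsv")
    truth_report(cohort.truth, outdir / "truth.tsv", cohort.config)
    for sample, per_caller in cohort.calls.items():
        for caller, caller_calls in per_caller.items():
            write_calls(caller_calls, outdir / "calls" / f"{sample}.{caller}.tsv")
    for sample, track in cohort.depth.items():
        write_depth_track(track, outdir / "depth" / f"{sample}.tsv")
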