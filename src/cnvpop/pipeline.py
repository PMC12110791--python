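"""Staged pipeline runner: simulate -> consensus -> cnvr -> genotype ->
annotate/qtl -> vst.

Stage bookkeeping is a plain-file manifest (``manifest.tsv`` in the work
directory): each completed stage records a hash of its parameters and of
its input files, plus output paths and row counts.  A rerun with unchanged
inputs and configuration skips completed stages; changing an input
invalidates that stage and everything downstream.  Outputs are written to
``<name>.partial`` and renamed on stage success, so an interrupted run
leaves its debris clearly marked.  Every output file starts with a
``#config_hash=`` comment tying it to the configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .annotation_overlap import classify_context, context_counts, intersect_qtl
from .call_processing import ConsensusPolicy, FilterPolicy, consensus_merge, filter_calls
from .cnvr_builder import (
    LengthPolicy,
    build_cnvrs,
    read_cnvr_table,
    summarize_landscape,
    write_cnvr_bed,
    write_cnvr_table,
)
from .genotyping import genotype_cnvrs, read_depth_track, read_matrix, write_matrix
from .io_formats import (
    CALLER_ROLES,
    ConfigError,
    read_calls,
    read_genome_layout,
    read_gff3,
    read_population_map,
    read_qtl_table,
    write_calls,
)
from .synthetic_data import SimConfig, simulate_cohort, write_cohort
from .vst_divergence import OutlierPolicy, call_outliers, mean_vst, vst_pairwise, write_vst_table

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "consensus", "cnvr", "genotype", "annotate", "qtl", "vst")


@dataclass
class PipelineConfig:
    workdir: str
    seed: int = 0
    simulate: bool = True
    inputs_dir: str | None = None  # defaults to <workdir>/inputs
    filter_policy: FilterPolicy = field(default_factory=FilterPolicy)
    consensus_policy: ConsensusPolicy = field(default_factory=ConsensusPolicy)
    length_policy: LengthPolicy = field(default_factory=LengthPolicy)
    outlier_policy: OutlierPolicy = field(default_factory=OutlierPolicy)
    flank: int = 1000
    max_qtl_span: int = 5_000_000
    sim: SimConfig | None = None  # populated from seed when simulate=True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.inputs_dir is None:
            self.inputs_dir = str(Path(self.workdir) / "inputs")
        if self.simulate and self.sim is None:
            self.sim = SimConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "workdir" not in raw:
            raise ConfigError(f"{path}: 'workdir' is required")
        kwargs = dict(raw)
        for key, klass in (
            ("filter_policy", FilterPolicy),
            ("consensus_policy", ConsensusPolicy),
            ("length_policy", LengthPolicy),
            ("outlier_policy", OutlierPolicy),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                try:
                    kwargs[key] = klass(**kwargs[key])
                except TypeError as exc:
                    raise ConfigError(f"{path}: bad {key}: {exc}") from exc
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Hash of the analytic parameters; output locations are excluded so
        the same configuration yields byte-identical outputs anywhere."""

        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, (list, tuple)):
                return [enc(x) for x in obj]
            return obj

        payload = enc(self)
        payload.pop("workdir", None)
        payload.pop("inputs_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _hash_files(paths: list[Path]) -> str:
    h = hashlib.sha256()
    for p in sorted(paths):
        h.update(str(p.name).encode())
        h.update(p.read_bytes())
    return h.hexdigest()[:16]


class _Manifest:
    COLS = ("stage", "params_hash", "inputs_hash", "outputs", "n_rows")

    def __init__(self, path: Path) -> None:
        self.path = path
        self.entries: dict[str, dict] = {}
        if path.exists():
            with open(path) as fh:
                header = fh.readline()
                for line in fh:
                    f = line.rstrip("\n").split("\t")
                    self.entries[f[0]] = dict(zip(self.COLS, f))

    def save(self) -> None:
        with open(self.path, "w") as fh:
            fh.write("\t".join(self.COLS) + "\n")
            for stage in STAGES:
                if stage in self.entries:
                    e = self.entries[stage]
                    fh.write("\t".join(str(e[c]) for c in self.COLS) + "\n")

    def up_to_date(self, stage: str, params_hash: str, inputs_hash: str) -> bool:
        e = self.entries.get(stage)
        if e is None or e["params_hash"] != params_hash or e["inputs_hash"] != inputs_hash:
            return False
        return all(Path(p).exists() for p in e["outputs"].split(";") if p)

    def record(self, stage, params_hash, inputs_hash, outputs, n_rows) -> None:
        self.entries[stage] = {
            "stage": stage,
            "params_hash": params_hash,
            "inputs_hash": inputs_hash,
            "outputs": ";".join(str(p) for p in outputs),
            "n_rows": str(n_rows),
        }
        self.save()


def _stamp(path: Path, config_hash: str) -> None:
    """Prepend the config-hash comment to a finished output file."""
    body = path.read_bytes()
    path.write_bytes(f"#config_hash={config_hash}\n".encode() + body)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order; returns the manifest entries."""
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(workdir / "run.log")
    root = logging.getLogger("cnvpop")
    root.addHandler(fh)
    try:
        return _run(config, workdir)
    finally:
        root.removeHandler(fh)
        fh.close()


def _run(config: PipelineConfig, workdir: Path) -> dict:
    manifest = _Manifest(workdir / "manifest.tsv")
    chash = config.config_hash()
    inputs_dir = Path(config.inputs_dir)

    def stage(name: str, input_paths: list[Path], run) -> None:
        params_hash = chash
        inputs_hash = _hash_files(input_paths) if input_paths else "-"
        if manifest.up_to_date(name, params_hash, inputs_hash):
            logger.info("stage %s: up to date, skipped", name)
            return
        logger.info("stage %s: running", name)
        try:
            outputs, n_rows = run()
        except Exception:
            logger.exception("stage %s failed", name)
            raise RuntimeError(f"pipeline halted at stage {name!r}")
        manifest.record(name, params_hash, inputs_hash, outputs, n_rows)
        logger.info("stage %s: %d row(s)", name, n_rows)

    # -- simulate -----------------------------------------------------------
    if config.simulate:
        def run_simulate():
            cohort = simulate_cohort(config.sim)
            write_cohort(cohort, inputs_dir)
            outputs = sorted(str(p) for p in inputs_dir.rglob("*.tsv"))
            return outputs + [str(inputs_dir / "genes.gff3")], len(cohort.truth)

        stage("simulate", [], run_simulate)

    layout = read_genome_layout(inputs_dir / "genome.tsv")
    pop_map_path = inputs_dir / "populations.tsv"
    pops = read_population_map(pop_map_path)
    samples = sorted(pops.assignments)

    # -- consensus ----------------------------------------------------------
    cons_dir = workdir / "consensus"
    call_files = sorted((inputs_dir / "calls").glob("*.tsv"))

    def run_consensus():
        cons_dir.mkdir(exist_ok=True)
        n = 0
        outputs = []
        for sample in samples:
            per_caller = {}
            for caller in CALLER_ROLES:
                path = inputs_dir / "calls" / f"{sample}.{caller}.tsv"
                if path.exists():
                    raw = read_calls(path, sample, caller, layout)
                    kept = filter_calls(raw, config.filter_policy)
                    logger.info("filter %s/%s: %d -> %d calls", sample, caller, len(raw), len(kept))
                    per_caller[caller] = kept
            merged = consensus_merge(per_caller, config.consensus_policy)
            out = cons_dir / f"{sample}.tsv"
            tmp = out.with_suffix(".tsv.partial")
            write_calls(merged, tmp)
            _stamp(tmp, chash)
            tmp.rename(out)
            outputs.append(str(out))
            n += len(merged)
        return outputs, n

    stage("consensus", call_files + [pop_map_path], run_consensus)

    # -- cnvr ---------------------------------------------------------------
    cnvr_table = workdir / "cnvr.tsv"
    cnvr_bed = workdir / "cnvr.bed"
    summary_path = workdir / "summary.tsv"
    cons_files = sorted(cons_dir.glob("*.tsv"))

    def run_cnvr():
        all_calls = []
        for sample in samples:
            all_calls.extend(read_calls(cons_dir / f"{sample}.tsv", sample, "CONSENSUS", layout))
        cnvrs = build_cnvrs(all_calls, config.length_policy, layout)
        summary = summarize_landscape(cnvrs, layout)
        for path, writer in (
            (cnvr_table, lambda p: write_cnvr_table(cnvrs, p)),
            (cnvr_bed, lambda p: write_cnvr_bed(cnvrs, p)),
            (summary_path, lambda p: _write_summary(summary, p)),
        ):
            tmp = path.with_name(path.name + ".partial")
            writer(tmp)
            _stamp(tmp, chash)
            tmp.rename(path)
        return [str(cnvr_table), str(cnvr_bed), str(summary_path)], len(cnvrs)

    stage("cnvr", cons_files, run_cnvr)

    cnvrs = read_cnvr_table(cnvr_table)

    # -- genotype -----------------------------------------------------------
    matrix_path = workdir / "cn_matrix.tsv"
    depth_files = sorted((inputs_dir / "depth").glob("*.tsv"))

    def run_genotype():
        tracks = {}
        for path in depth_files:
            track = read_depth_track(path)
            tracks[track.sample_id] = track
        matrix = genotype_cnvrs(cnvrs, tracks)
        tmp = matrix_path.with_name(matrix_path.name + ".partial")
        write_matrix(matrix, tmp)
        _stamp(tmp, chash)
        tmp.rename(matrix_path)
        return [str(matrix_path)], len(matrix.cnvr_ids)

    stage("genotype", [cnvr_table] + depth_files, run_genotype)

    # -- annotate -----------------------------------------------------------
    context_path = workdir / "context.tsv"
    gff_path = inputs_dir / "genes.gff3"

    def run_annotate():
        genes = read_gff3(gff_path)
        contexts = classify_context(cnvrs, genes, flank=config.flank)
        counts = context_counts(contexts)
        tmp = context_path.with_name(context_path.name + ".partial")
        with open(tmp, "w") as out:
            out.write("cnvr_id\tcontext\tgenes_within_flank\n")
            for c in contexts:
                out.write(f"{c.cnvr_id}\t{c.context}\t{','.join(sorted(c.genes_within_flank))}\n")
        _stamp(tmp, chash)
        tmp.rename(context_path)
        logger.info("context counts: %s", counts)
        return [str(context_path)], len(contexts)

    stage("annotate", [cnvr_table, gff_path], run_annotate)

    # -- qtl ----------------------------------------------------------------
    qtl_path = inputs_dir / "qtls.tsv"
    qtl_out = workdir / "qtl_overlap.tsv"

    def run_qtl():
        qtls = read_qtl_table(qtl_path)
        pairs_q, summary = intersect_qtl(cnvrs, qtls, config.max_qtl_span)
        tmp = qtl_out.with_name(qtl_out.name + ".partial")
        with open(tmp, "w") as out:
            out.write(f"#n_cnvrs_overlapping\t{summary.n_cnvrs_overlapping}\n")
            out.write(f"#n_qtls_overlapped\t{summary.n_qtls_overlapped}\n")
            out.write("cnvr_id\tqtl_id\ttrait_name\toverlap_bp\n")
            for p in pairs_q:
                out.write(f"{p.cnvr_id}\t{p.qtl_id}\t{p.trait_name}\t{p.overlap_bp}\n")
        _stamp(tmp, chash)
        tmp.rename(qtl_out)
        return [str(qtl_out)], len(pairs_q)

    stage("qtl", [cnvr_table, qtl_path], run_qtl)

    # -- vst ----------------------------------------------------------------
    vst_path = workdir / "vst.tsv"
    outlier_path = workdir / "vst_outliers.tsv"

    def run_vst():
        matrix = read_matrix(matrix_path)
        coords = {c.cnvr_id: (c.chrom, c.start, c.end) for c in cnvrs}
        all_records = []
        outlier_rows = []
        for pair in pops.pairs():
            records = vst_pairwise(matrix, pops, pair)
            all_records.extend(records)
            ids, threshold = call_outliers(records, config.outlier_policy)
            logger.info(
                "vst %s-%s: mean %.4f, %d outlier(s) at threshold %.4f",
                pair[0], pair[1], mean_vst(records), len(ids), threshold,
            )
            for cnvr_id in ids:
                outlier_rows.append((pair, cnvr_id, threshold))
        tmp = vst_path.with_name(vst_path.name + ".partial")
        write_vst_table(all_records, tmp, coords)
        _stamp(tmp, chash)
        tmp.rename(vst_path)
        tmp2 = outlier_path.with_name(outlier_path.name + ".partial")
        with open(tmp2, "w") as out:
            out.write("pair\tcnvr_id\tthreshold\n")
            for pair, cnvr_id, threshold in outlier_rows:
                out.write(f"{pair[0]}-{pair[1]}\t{cnvr_id}\t{threshold!r}\n")
        _stamp(tmp2, chash)
        tmp2.rename(outlier_path)
        return [str(vst_path), str(outlier_path)], len(all_records)

    stage("vst", [matrix_path, cnvr_table, pop_map_path], run_vst)

    return manifest.entries


def _write_summary(summary, path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for name in ("n_total", "n_gain", "n_loss", "n_both", "total_len", "mean_len"):
            fh.write(f"{name}\t{getattr(summary, name)}\n")
        fh.write(f"mean_len_exact\t{summary.mean_len_exact!r}\n")
        fh.write(f"genome_fraction\t{summary.genome_fraction!r}\n")
        for label, count in summary.size_class_counts.items():
            fh.write(f"size_{label}\t{count}\n")
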