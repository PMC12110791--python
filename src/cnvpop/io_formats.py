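"""Readers and writers for every external file the pipeline touches.

All coordinates are held internally as 0-based half-open intervals
(BED-like).  Formats that use other conventions (GFF3: 1-based inclusive)
are converted at the I/O boundary, never downstream.  Chromosome names are
matched by exact string comparison; no "chr" prefix normalisation is
attempted, because silent renaming corrupts overlap counts.

Readers validate aggressively and report the offending line number, since
malformed structural-variant tables are the rule rather than the exception
in the wild.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "DataError",
    "ConfigError",
    "CALLER_ROLES",
    "CONSENSUS_CALLER",
    "SVTYPES",
    "GenomeLayout",
    "CnvCall",
    "GeneModel",
    "QtlRecord",
    "PopulationMap",
    "read_calls",
    "write_calls",
    "read_gff3",
    "write_gff3",
    "read_qtl_table",
    "write_qtl_table",
    "read_population_map",
    "write_population_map",
    "read_genome_layout",
    "write_genome_layout",
]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class ConfigError(ValueError):
    """Invalid configuration."""


#: Caller roles rather than tool names: a read-depth caller, a discordant/
#: split-read-pair caller, and a population-aware read-depth caller.  The
#: pipeline only ever sees their output files, never runs the tools.
CALLER_ROLES = ("RD", "PAIRED", "POPRD")

#: Synthetic caller label given to consensus calls emitted by the merge step.
CONSENSUS_CALLER = "CONSENSUS"

SVTYPES = ("DEL", "DUP")


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths defining the coordinate space."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise DataError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise DataError("duplicate chromosome names in layout")
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            if length < 1:
                raise DataError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names

    def chrom_order(self, chrom: str) -> int:
        return self.chrom_names.index(chrom)


@dataclass
class CnvCall:
    """A single caller's CNV call in one sample.

    ``pval`` and ``q0`` carry the read-depth caller's call-quality metrics
    (the fraction of zero-mapping-quality reads for ``q0``); ``est_cn`` is
    the caller's own copy-number estimate where it reports one.  Any of the
    three may be missing (``None``).
    """

    sample_id: str
    caller: str
    chrom: str
    start: int
    end: int
    svtype: str
    pval: float | None = None
    q0: float | None = None
    est_cn: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise DataError(
                f"call interval end <= start ({self.chrom}:{self.start}-{self.end})"
            )
        if self.svtype not in SVTYPES:
            raise DataError(f"unknown svtype {self.svtype!r}")
        for name in ("pval", "q0"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise DataError(f"{name}={v} outside [0, 1]")
        if self.est_cn is not None and self.est_cn < 0:
            raise DataError(f"est_cn={self.est_cn} negative")

    @property
    def length(self) -> int:
        return self.end - self.start

    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise DataError(f"gene {self.gene_id}: end <= start")
        if self.strand not in ("+", "-"):
            raise DataError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        self.exons = sorted(self.exons)
        prev_end = None
        for (s, e) in self.exons:
            if s < self.start or e > self.end:
                raise DataError(f"gene {self.gene_id}: exon ({s},{e}) outside gene span")
            if prev_end is not None and s < prev_end:
                raise DataError(f"gene {self.gene_id}: overlapping exons after sorting")
            prev_end = e


@dataclass
class QtlRecord:
    qtl_id: str
    trait_name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise DataError(f"QTL {self.qtl_id}: end <= start")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class PopulationMap:
    """sample_id -> population label, with convenience accessors."""

    assignments: dict[str, str]

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for pop in self.assignments.values():
            out[pop] = out.get(pop, 0) + 1
        return out

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    def samples_in(self, pop: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == pop]

    def pairs(self) -> list[tuple[str, str]]:
        pops = self.populations
        return [(a, b) for i, a in enumerate(pops) for b in pops[i + 1 :]]

    def __getitem__(self, sample: str) -> str:
        return self.assignments[sample]


# ---------------------------------------------------------------------------
# Helpers

_MISSING_TOKENS = {"", ".", "NA", "NaN", "nan", "None"}


def _opt_float(token: str, line_no: int, col: str) -> float | None:
    if token in _MISSING_TOKENS:
        return None
    try:
        return float(token)
    except ValueError as exc:
        raise DataError(f"line {line_no}: column {col!r}: not a number: {token!r}") from exc


def _fmt_opt(v: float | None) -> str:
    return "" if v is None else repr(float(v))


def _data_rows(path: Path) -> Iterable[tuple[int, list[str]]]:
    """Yield (line_number, fields) for tab-separated rows, skipping comments."""
    with open(path, newline="") as fh:
        for line_no, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (row[0].startswith("#")):
                continue
            yield line_no, row


# ---------------------------------------------------------------------------
# CNV call tables

_CALL_REQUIRED = ["chrom", "start", "end", "svtype"]
_CALL_OPTIONAL = ["pval", "q0", "est_cn"]


def read_calls(
    path: str | Path,
    sample_id: str,
    caller: str,
    layout: GenomeLayout | None = None,
) -> list[CnvCall]:
    """Read one sample's calls from one caller.

    The file is tab-separated with a header line naming at least
    ``chrom  start  end  svtype``; the quality columns ``pval``, ``q0`` and
    ``est_cn`` are optional and yield missing fields when absent.  Records
    are returned in file order.  Malformed coordinates, unknown svtypes and
    chromosomes outside ``layout`` are rejected with the line number.
    """
    path = Path(path)
    rows = _data_rows(path)
    try:
        header_no, header = next(iter(rows))
    except StopIteration:
        raise DataError(f"{path}: empty file, expected a header line")
    for col in _CALL_REQUIRED:
        if col not in header:
            raise DataError(f"{path}: missing required column {col!r}")
    idx = {c: header.index(c) for c in header}
    calls: list[CnvCall] = []
    for line_no, row in rows:
        if len(row) < len(_CALL_REQUIRED):
            raise DataError(f"{path}: line {line_no}: expected >= 4 fields, got {len(row)}")

        def get(col: str) -> str:
            i = idx.get(col)
            return row[i] if i is not None and i < len(row) else ""

        try:
            start = int(get("start"))
            end = int(get("end"))
        except ValueError as exc:
            raise DataError(f"{path}: line {line_no}: malformed coordinates") from exc
        chrom = get("chrom")
        if layout is not None and chrom not in layout:
            raise DataError(f"{path}: line {line_no}: unknown chromosome {chrom!r}")
        svtype = get("svtype")
        try:
            call = CnvCall(
                sample_id=sample_id,
                caller=caller,
                chrom=chrom,
                start=start,
                end=end,
                svtype=svtype,
                pval=_opt_float(get("pval"), line_no, "pval"),
                q0=_opt_float(get("q0"), line_no, "q0"),
                est_cn=_opt_float(get("est_cn"), line_no, "est_cn"),
            )
        except DataError as exc:
            raise DataError(f"{path}: line {line_no}: {exc}") from exc
        calls.append(call)
    return calls


def write_calls(calls: Sequence[CnvCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_CALL_REQUIRED + _CALL_OPTIONAL)
        for c in calls:
            w.writerow(
                [c.chrom, c.start, c.end, c.svtype, _fmt_opt(c.pval), _fmt_opt(c.q0), _fmt_opt(c.est_cn)]
            )


# ---------------------------------------------------------------------------
# GFF3 genes

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene and exon features from a GFF3 file.

    GFF3 coordinates are 1-based inclusive; they are converted to 0-based
    half-open here.  Exons are attached to their parent gene through the
    ``Parent`` attribute chain (directly or via an mRNA); overlapping exon
    intervals from alternative transcripts are collapsed to their union so
    that each gene carries a non-overlapping exon set.  An exon whose parent
    cannot be resolved to a gene is skipped with a warning; duplicated gene
    IDs are an error.
    """
    import gffutils

    path = Path(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    gene_ids_seen: dict[str, int] = {}
    genes: list[GeneModel] = []
    gene_keys: dict[str, str] = {}  # db key -> gene_id
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = feat.attributes.get("ID", [feat.id])[0]
        gene_ids_seen[gid] = gene_ids_seen.get(gid, 0) + 1
        if gene_ids_seen[gid] > 1:
            raise DataError(f"{path}: duplicate gene ID {gid!r}")
        gene_keys[feat.id] = gid
        name = feat.attributes.get("Name", [gid])[0]
        biotype = feat.attributes.get(
            "biotype", feat.attributes.get("gene_biotype", ["protein_coding"])
        )[0]
        exon_iv: list[tuple[int, int]] = []
        for exon in db.children(feat.id, featuretype="exon"):
            exon_iv.append((exon.start - 1, exon.end))
        genes.append(
            GeneModel(
                gene_id=gid,
                gene_name=name,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                exons=_union_intervals(exon_iv),
                biotype=biotype,
            )
        )
    # exons that never reach a gene ancestor
    n_orphan = 0
    for exon in db.features_of_type("exon"):
        if not any(p.featuretype == "gene" for p in db.parents(exon.id)):
            n_orphan += 1
    if n_orphan:
        warnings.warn(f"{path}: skipped {n_orphan} exon(s) without a resolvable gene parent")
    if not genes:
        warnings.warn(f"{path}: no gene features found")
    return genes


def _union_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write genes and their exons as GFF3 (converting back to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};Name={g.gene_name};biotype={g.biotype}"
            fh.write(
                f"{g.chrom}\tcnvpop\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tcnvpop\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# QTL tables

_QTL_COLS = ["qtl_id", "trait_name", "chrom", "start", "end"]


def read_qtl_table(path: str | Path) -> list[QtlRecord]:
    path = Path(path)
    rows = _data_rows(path)
    try:
        _, header = next(iter(rows))
    except StopIteration:
        raise DataError(f"{path}: empty QTL table")
    for col in _QTL_COLS:
        if col not in header:
            raise DataError(f"{path}: missing QTL column {col!r}")
    idx = {c: header.index(c) for c in _QTL_COLS}
    out: list[QtlRecord] = []
    for line_no, row in rows:
        try:
            out.append(
                QtlRecord(
                    qtl_id=row[idx["qtl_id"]],
                    trait_name=row[idx["trait_name"]],
                    chrom=row[idx["chrom"]],
                    start=int(row[idx["start"]]),
                    end=int(row[idx["end"]]),
                )
            )
        except (ValueError, IndexError, DataError) as exc:
            raise DataError(f"{path}: line {line_no}: {exc}") from exc
    return out


def write_qtl_table(qtls: Sequence[QtlRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_QTL_COLS)
        for q in qtls:
            w.writerow([q.qtl_id, q.trait_name, q.chrom, q.start, q.end])


# ---------------------------------------------------------------------------
# Population map

def read_population_map(path: str | Path) -> PopulationMap:
    path = Path(path)
    assignments: dict[str, str] = {}
    rows = _data_rows(path)
    try:
        _, header = next(iter(rows))
    except StopIteration:
        raise DataError(f"{path}: empty population map")
    if header[:2] != ["sample_id", "population"]:
        raise DataError(f"{path}: expected header 'sample_id\\tpopulation'")
    for line_no, row in rows:
        if len(row) < 2:
            raise DataError(f"{path}: line {line_no}: expected 2 fields")
        sample, pop = row[0], row[1]
        if sample in assignments:
            raise DataError(f"{path}: line {line_no}: duplicate sample {sample!r}")
        assignments[sample] = pop
    return PopulationMap(assignments)


def write_population_map(pops: PopulationMap, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "population"])
        for sample, pop in pops.assignments.items():
            w.writerow([sample, pop])


# ---------------------------------------------------------------------------
# Genome layout

def read_genome_layout(path: str | Path) -> GenomeLayout:
    path = Path(path)
    names: list[str] = []
    lengths: list[int] = []
    rows = _data_rows(path)
    try:
        _, header = next(iter(rows))
    except StopIteration:
        raise DataError(f"{path}: empty genome layout")
    if header[:2] != ["chrom", "length"]:
        raise DataError(f"{path}: expected header 'chrom\\tlength'")
    for line_no, row in rows:
        try:
            names.append(row[0])
            lengths.append(int(row[1]))
        except (ValueError, IndexError) as exc:
            raise DataError(f"{path}: line {line_no}: {exc}") from exc
    return GenomeLayout(tuple(names), tuple(lengths))


def write_genome_layout(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["chrom", "length"])
        for name, length in zip(layout.chrom_names, layout.chrom_lengths):
            w.writerow([name, length])
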