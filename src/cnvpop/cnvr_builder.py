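"""Cohort-level CNV region (CNVR) construction and landscape summaries.

A CNVR is the union of transitively overlapping calls across all samples:
any shared base (>= 1 bp, regardless of deletion/duplication type) links
two calls, and each maximal linked set collapses to one region spanning the
minimum start and maximum end.  Regions are classified as *gain* (only
duplications observed), *loss* (only deletions) or *both*, and then subject
to class-specific length caps: loss and mixed regions above 50 kb, and gain
regions above 500 kb, are discarded outright — truncation would invent
breakpoints that no caller reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .io_formats import CnvCall, ConfigError, GenomeLayout

__all__ = [
    "Cnvr",
    "LengthPolicy",
    "LandscapeSummary",
    "SIZE_BINS",
    "build_cnvrs",
    "summarize_landscape",
    "write_cnvr_bed",
    "read_cnvr_bed",
    "write_cnvr_table",
    "read_cnvr_table",
]

#: Half-open length bins (bp) used for the size histogram: 0-2 kb, 2-5 kb,
#: 5-10 kb and everything of 10 kb and above.
SIZE_BINS = ((0, 2000), (2000, 5000), (5000, 10000), (10000, None))

CNVR_CLASSES = ("gain", "loss", "both")


@dataclass
class Cnvr:
    """A merged copy-number variable region with its carriers."""

    cnvr_id: str
    chrom: str
    start: int
    end: int
    cnvr_class: str
    carriers: dict[str, set[str]] = field(default_factory=dict)
    n_calls: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.cnvr_id}: end <= start")
        if self.cnvr_class not in CNVR_CLASSES:
            raise ValueError(f"{self.cnvr_id}: unknown class {self.cnvr_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)


@dataclass(frozen=True)
class LengthPolicy:
    """Class-specific maximum CNVR lengths; regions above the cap are dropped."""

    max_len_loss: int = 50_000
    max_len_both: int = 50_000
    max_len_gain: int = 500_000

    def __post_init__(self) -> None:
        if min(self.max_len_loss, self.max_len_both, self.max_len_gain) <= 0:
            raise ConfigError("length caps must be positive")

    def cap(self, cnvr_class: str) -> int:
        return {
            "loss": self.max_len_loss,
            "both": self.max_len_both,
            "gain": self.max_len_gain,
        }[cnvr_class]


@dataclass
class LandscapeSummary:
    n_total: int
    n_gain: int
    n_loss: int
    n_both: int
    total_len: int
    mean_len: int  # floor of the exact mean, matching integer-bp reporting
    mean_len_exact: float
    genome_fraction: float
    size_class_counts: dict[str, int]
    empty: bool = False


def _classify(svtypes: set[str]) -> str:
    if svtypes == {"DUP"}:
        return "gain"
    if svtypes == {"DEL"}:
        return "loss"
    return "both"


def build_cnvrs(
    calls: Sequence[CnvCall],
    policy: LengthPolicy | None = None,
    layout: GenomeLayout | None = None,
) -> list[Cnvr]:
    """Collapse cohort-wide calls into CNVRs.

    Per chromosome the calls are sorted by start and swept: a call starting
    strictly before the current region's end (half-open intervals — a call
    starting exactly at the end does not share a base) extends the region.
    ``policy=None`` disables the length caps, which is useful for auditing
    how many raw regions the caps remove.  Ids are assigned in genomic
    order; with a ``layout`` the chromosome order follows it, otherwise
    chromosomes sort lexicographically.
    """
    by_chrom: dict[str, list[CnvCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)

    if layout is not None:
        chrom_key = layout.chrom_order
    else:
        chrom_key = None

    chroms = sorted(by_chrom, key=chrom_key) if chrom_key else sorted(by_chrom)

    regions: list[tuple[str, int, int, list[CnvCall]]] = []
    for chrom in chroms:
        chrom_calls = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end))
        cur_start, cur_end = chrom_calls[0].start, chrom_calls[0].end
        members = [chrom_calls[0]]
        for c in chrom_calls[1:]:
            if c.start < cur_end:
                cur_end = max(cur_end, c.end)
                members.append(c)
            else:
                regions.append((chrom, cur_start, cur_end, members))
                cur_start, cur_end, members = c.start, c.end, [c]
        regions.append((chrom, cur_start, cur_end, members))

    out: list[Cnvr] = []
    idx = 1
    for chrom, start, end, members in regions:
        svtypes = {c.svtype for c in members}
        cls = _classify(svtypes)
        if policy is not None and (end - start) > policy.cap(cls):
            continue
        carriers: dict[str, set[str]] = {}
        for c in members:
            carriers.setdefault(c.sample_id, set()).add(c.svtype)
        out.append(
            Cnvr(
                cnvr_id=f"cnvr_{idx}",
                chrom=chrom,
                start=start,
                end=end,
                cnvr_class=cls,
                carriers=carriers,
                n_calls=len(members),
            )
        )
        idx += 1
    return out


def summarize_landscape(cnvrs: Sequence[Cnvr], genome: GenomeLayout) -> LandscapeSummary:
    """Counts, lengths, genome coverage and the size-class histogram."""
    bin_labels = [
        f"[{lo},{hi})" if hi is not None else f"[{lo},inf)" for lo, hi in SIZE_BINS
    ]
    counts = dict.fromkeys(bin_labels, 0)
    if not cnvrs:
        return LandscapeSummary(
            n_total=0, n_gain=0, n_loss=0, n_both=0, total_len=0,
            mean_len=0, mean_len_exact=0.0, genome_fraction=0.0,
            size_class_counts=counts, empty=True,
        )
    n_gain = sum(c.cnvr_class == "gain" for c in cnvrs)
    n_loss = sum(c.cnvr_class == "loss" for c in cnvrs)
    n_both = sum(c.cnvr_class == "both" for c in cnvrs)
    total_len = sum(c.length for c in cnvrs)
    for c in cnvrs:
        for label, (lo, hi) in zip(bin_labels, SIZE_BINS):
            if c.length >= lo and (hi is None or c.length < hi):
                counts[label] += 1
                break
    mean_exact = total_len / len(cnvrs)
    return LandscapeSummary(
        n_total=len(cnvrs),
        n_gain=n_gain,
        n_loss=n_loss,
        n_both=n_both,
        total_len=total_len,
        mean_len=int(mean_exact),
        mean_len_exact=mean_exact,
        genome_fraction=total_len / genome.total_length,
        size_class_counts=counts,
    )


# ---------------------------------------------------------------------------
# CNVR I/O.  Two formats: a BED6 export for interoperability (name = CNVR
# id, score = carrier count, strand ".") and a full-fidelity TSV that
# round-trips the carrier sets.

def write_cnvr_bed(cnvrs: Sequence[Cnvr], path) -> None:
    with open(path, "w") as fh:
        for c in cnvrs:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.cnvr_id}\t{c.n_carriers}\t.\n")


def read_cnvr_bed(path) -> list[Cnvr]:
    """Read the BED6 export back.

    BED carries no class or carrier detail; regions come back with class
    ``both`` as a neutral placeholder, anonymous carriers preserving the
    carrier count, and ``n_calls=0``.  Use the TSV table for full fidelity.
    """
    out: list[Cnvr] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end, name, score, _strand = line.rstrip("\n").split("\t")[:6]
            out.append(
                Cnvr(
                    cnvr_id=name,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    cnvr_class="both",
                    carriers={f"_carrier{i}": set() for i in range(int(score))},
                )
            )
    return out


def write_cnvr_table(cnvrs: Sequence[Cnvr], path) -> None:
    with open(path, "w") as fh:
        fh.write("cnvr_id\tchrom\tstart\tend\tclass\tn_calls\tcarriers\n")
        for c in cnvrs:
            carriers = ";".join(
                f"{s}:{','.join(sorted(types))}" for s, types in sorted(c.carriers.items())
            )
            fh.write(
                f"{c.cnvr_id}\t{c.chrom}\t{c.start}\t{c.end}\t{c.cnvr_class}\t{c.n_calls}\t{carriers}\n"
            )


def read_cnvr_table(path) -> list[Cnvr]:
    out: list[Cnvr] = []
    with open(path) as fh:
        header = None
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            if header is None:
                header = line.rstrip("\n").split("\t")
                continue
            cnvr_id, chrom, start, end, cls, n_calls, carrier_str = line.rstrip("\n").split("\t")
            carriers: dict[str, set[str]] = {}
            if carrier_str:
                for entry in carrier_str.split(";"):
                    sample, types = entry.split(":")
                    carriers[sample] = set(types.split(","))
            out.append(
                Cnvr(
                    cnvr_id=cnvr_id,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    cnvr_class=cls,
                    carriers=carriers,
                    n_calls=int(n_calls),
                )
            )
    return out
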