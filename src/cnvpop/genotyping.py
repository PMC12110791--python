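"""Read-depth copy-number genotyping of CNVRs.

For a diploid genome the copy number of a region is estimated as

    CN = 2 * r / m

where ``m`` is the sample's global mean windowed depth and ``r`` the
length-weighted mean depth of the windows overlapping the region (windows
partially covered by the region contribute in proportion to the overlap).
The estimator is scale-invariant in the per-sample sequencing depth, needs
no integer rounding, and fills the dense CNVR x sample matrix that the Vst
scan consumes.  ``m`` deliberately uses *all* windows: with CNVRs covering
a percent or two of the genome the contamination of the baseline is
negligible and the estimator stays simple; the residual bias is documented
in the methods note.

No GC-content correction is applied; ``correction`` accepts a callback for
data that needs one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cnvr_builder import Cnvr
from .io_formats import DataError

__all__ = [
    "DepthTrack",
    "CnMatrix",
    "genotype_cnvrs",
    "write_matrix",
    "read_matrix",
    "write_depth_track",
    "read_depth_track",
]


@dataclass
class DepthTrack:
    """Windowed read counts for one sample, one vector per chromosome."""

    sample_id: str
    window_size: int
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise DataError("window_size must be >= 1")
        for chrom, arr in self.counts.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 1:
                raise DataError(f"{chrom}: counts must be a 1-D vector")
            if np.any(arr < 0):
                raise DataError(f"{chrom}: negative window counts")
            self.counts[chrom] = arr

    def n_windows(self, chrom: str) -> int:
        return len(self.counts[chrom])

    def global_mean(self) -> float:
        all_counts = np.concatenate([v for v in self.counts.values()]) if self.counts else np.array([])
        if all_counts.size == 0:
            raise DataError(f"{self.sample_id}: empty depth track")
        return float(all_counts.mean())


@dataclass
class CnMatrix:
    """CNVR x sample real-valued copy numbers with an imputation mask.

    ``values`` is dense; cells that could not be genotyped (no depth
    coverage) hold the diploid default 2.0 and are flagged in ``mask``.
    """

    values: pd.DataFrame
    mask: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.mask.index) or not self.values.columns.equals(
            self.mask.columns
        ):
            raise DataError("values and mask must share index and columns")
        if (self.values.to_numpy() < 0).any():
            raise DataError("negative copy numbers")

    @property
    def cnvr_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def n_masked(self) -> int:
        return int(self.mask.to_numpy().sum())


def genotype_cnvrs(
    cnvrs: Sequence[Cnvr],
    tracks: Mapping[str, DepthTrack],
    correction: Callable[[str, np.ndarray], np.ndarray] | None = None,
) -> CnMatrix:
    """Estimate CN per CNVR per sample from windowed depth.

    Raises on a degenerate (all-zero) track.  A CNVR on a chromosome the
    track does not cover gets the imputed diploid value with the mask set.
    """
    sample_ids = sorted(tracks)
    cnvr_ids = [c.cnvr_id for c in cnvrs]
    values = np.full((len(cnvrs), len(sample_ids)), 2.0)
    mask = np.zeros_like(values, dtype=bool)

    for j, sample in enumerate(sample_ids):
        track = tracks[sample]
        counts = track.counts
        if correction is not None:
            counts = {chrom: correction(chrom, arr) for chrom, arr in counts.items()}
        m = (
            float(np.concatenate(list(counts.values())).mean())
            if counts
            else 0.0
        )
        if m == 0.0:
            raise DataError(f"{sample}: degenerate depth track (global mean depth is 0)")
        w = track.window_size
        for i, cnvr in enumerate(cnvrs):
            arr = counts.get(cnvr.chrom)
            if arr is None:
                mask[i, j] = True
                continue
            i0 = cnvr.start // w
            i1 = min(math.ceil(cnvr.end / w), len(arr))
            if i1 <= i0:
                mask[i, j] = True
                continue
            idx = np.arange(i0, i1)
            win_starts = idx * w
            win_ends = win_starts + w
            weights = np.minimum(cnvr.end, win_ends) - np.maximum(cnvr.start, win_starts)
            weights = np.clip(weights, 0, None).astype(float)
            wsum = weights.sum()
            if wsum == 0:
                mask[i, j] = True
                continue
            r = float((weights * arr[i0:i1]).sum() / wsum)
            values[i, j] = 2.0 * r / m

    return CnMatrix(
        values=pd.DataFrame(values, index=cnvr_ids, columns=sample_ids),
        mask=pd.DataFrame(mask, index=cnvr_ids, columns=sample_ids),
    )


# ---------------------------------------------------------------------------
# I/O: wide TSV for the matrix (masked cells listed in '#masked' comment
# lines so one file round-trips), and a window BED-like TSV for depth.

def write_matrix(matrix: CnMatrix, path) -> None:
    with open(path, "w") as fh:
        rows, cols = np.nonzero(matrix.mask.to_numpy())
        for r, c in zip(rows, cols):
            fh.write(f"#masked\t{matrix.cnvr_ids[r]}\t{matrix.sample_ids[c]}\n")
        fh.write("cnvr_id\t" + "\t".join(matrix.sample_ids) + "\n")
        vals = matrix.values.to_numpy()
        for i, cnvr_id in enumerate(matrix.cnvr_ids):
            fh.write(cnvr_id + "\t" + "\t".join(repr(float(v)) for v in vals[i]) + "\n")


def read_matrix(path) -> CnMatrix:
    masked: list[tuple[str, str]] = []
    header: list[str] | None = None
    ids: list[str] = []
    data: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#masked\t"):
                _, cnvr_id, sample = line.split("\t")
                masked.append((cnvr_id, sample))
                continue
            if line.startswith("#") or not line:
                continue
            fields = line.split("\t")
            if header is None:
                header = fields[1:]
                continue
            ids.append(fields[0])
            data.append([float(x) for x in fields[1:]])
    if header is None:
        raise DataError(f"{path}: empty matrix file")
    values = pd.DataFrame(data, index=ids, columns=header)
    mask = pd.DataFrame(False, index=ids, columns=header)
    for cnvr_id, sample in masked:
        mask.loc[cnvr_id, sample] = True
    return CnMatrix(values=values, mask=mask)


def write_depth_track(track: DepthTrack, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#sample_id\t{track.sample_id}\n")
        fh.write(f"#window_size\t{track.window_size}\n")
        fh.write("chrom\tstart\tend\tcount\n")
        w = track.window_size
        for chrom, arr in track.counts.items():
            for i, v in enumerate(arr):
                fh.write(f"{chrom}\t{i * w}\t{(i + 1) * w}\t{float(v)!r}\n")


def read_depth_track(path) -> DepthTrack:
    sample_id = None
    window_size = None
    counts: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#sample_id\t"):
                sample_id = line.split("\t")[1]
                continue
            if line.startswith("#window_size\t"):
                window_size = int(line.split("\t")[1])
                continue
            if line.startswith("#") or not line or line.startswith("chrom\t"):
                continue
            chrom, _start, _end, count = line.split("\t")
            counts.setdefault(chrom, []).append(float(count))
    if sample_id is None or window_size is None:
        raise DataError(f"{path}: missing '#sample_id' / '#window_size' header lines")
    return DepthTrack(
        sample_id=sample_id,
        window_size=window_size,
        counts={c: np.asarray(v, dtype=float) for c, v in counts.items()},
    )
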