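"""Per-call retention filters and per-sample multi-caller consensus.

The filter mirrors the standard read-depth caller post-processing: keep a
call only if its p-value is below ``max_pval``, its fraction of
zero-mapping-quality reads (q0) is below ``max_q0``, and the call spans
strictly more than ``min_len`` bp.  Quality fields a caller does not report
are treated as vacuously passing, so split-read callers that emit neither
p-values nor q0 are filtered on length alone.

The consensus step replaces an external SV-merging tool: calls from
different callers in the same sample are linked when they reciprocally
overlap at ``min_reciprocal_overlap`` (and share a type, if required);
connected components supported by enough distinct callers — including the
anchor caller, by default the population-aware read-depth role — collapse
to one representative call at the per-coordinate medians.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Mapping, Sequence

from .io_formats import CALLER_ROLES, CONSENSUS_CALLER, CnvCall, ConfigError

__all__ = [
    "FilterPolicy",
    "ConsensusPolicy",
    "filter_calls",
    "consensus_merge",
    "reciprocal_overlap",
]


@dataclass(frozen=True)
class FilterPolicy:
    """Retention thresholds for individual CNV calls.

    Defaults: p-value < 0.001, q0 < 0.5, length strictly greater than
    1000 bp ("exceeding 1 kb", so a 1000 bp call is removed).
    """

    max_pval: float = 0.001
    max_q0: float = 0.5
    min_len: int = 1000

    def __post_init__(self) -> None:
        if self.max_pval <= 0 or self.max_q0 <= 0:
            raise ConfigError("filter thresholds must be positive")
        if self.min_len < 1:
            raise ConfigError("min_len must be >= 1")

    def keep(self, call: CnvCall) -> bool:
        if call.pval is not None and not call.pval < self.max_pval:
            return False
        if call.q0 is not None and not call.q0 < self.max_q0:
            return False
        return call.length > self.min_len


@dataclass(frozen=True)
class ConsensusPolicy:
    """How per-caller call sets are merged within one sample."""

    min_callers: int = 2
    min_reciprocal_overlap: float = 0.5
    require_same_type: bool = True
    anchor_caller: str | None = "POPRD"

    def __post_init__(self) -> None:
        if not 1 <= self.min_callers <= len(CALLER_ROLES):
            raise ConfigError(f"min_callers must be in [1, {len(CALLER_ROLES)}]")
        if not 0.0 < self.min_reciprocal_overlap <= 1.0:
            raise ConfigError("min_reciprocal_overlap must be in (0, 1]")


def filter_calls(calls: Sequence[CnvCall], policy: FilterPolicy) -> list[CnvCall]:
    """Pure filter: returns the retained subset in the original order."""
    return [c for c in calls if policy.keep(c)]


def reciprocal_overlap(a: CnvCall, b: CnvCall) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 when on different chromosomes."""
    if a.chrom != b.chrom:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def consensus_merge(
    per_caller_calls: Mapping[str, Sequence[CnvCall]],
    policy: ConsensusPolicy = ConsensusPolicy(),
) -> list[CnvCall]:
    """Merge one sample's per-caller call sets into consensus calls.

    Same-type calls (when ``require_same_type``) from *different* callers
    whose reciprocal overlap reaches the threshold are connected; each
    connected component seen by >= ``min_callers`` distinct callers (and by
    the anchor caller, when one is set) emits a single consensus call
    spanning the component's median start and median end, rounded down.
    The consensus p-value is the members' minimum, q0 their maximum, and
    est_cn the mean over members that report one.
    """
    flat: list[tuple[str, CnvCall]] = [
        (caller, call)
        for caller in sorted(per_caller_calls)
        for call in per_caller_calls[caller]
    ]
    n = len(flat)
    uf = _UnionFind(n)
    for i in range(n):
        ci, a = flat[i]
        for j in range(i + 1, n):
            cj, b = flat[j]
            if ci == cj:
                continue
            if policy.require_same_type and a.svtype != b.svtype:
                continue
            if reciprocal_overlap(a, b) >= policy.min_reciprocal_overlap:
                uf.union(i, j)

    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(uf.find(i), []).append(i)

    sample_ids = {call.sample_id for _, call in flat}
    if len(sample_ids) > 1:
        raise ValueError(f"consensus_merge expects one sample, got {sorted(sample_ids)}")

    out: list[CnvCall] = []
    for members in components.values():
        callers = {flat[i][0] for i in members}
        if len(callers) < policy.min_callers:
            continue
        if policy.anchor_caller is not None and policy.anchor_caller not in callers:
            continue
        calls = [flat[i][1] for i in members]
        start = math.floor(statistics.median(c.start for c in calls))
        end = math.floor(statistics.median(c.end for c in calls))
        svtypes = sorted({c.svtype for c in calls})
        if len(svtypes) > 1:
            # only reachable with require_same_type=False: majority type,
            # ties broken lexicographically
            counts = {t: sum(c.svtype == t for c in calls) for t in svtypes}
            svtype = max(svtypes, key=lambda t: (counts[t], t))
        else:
            svtype = svtypes[0]
        pvals = [c.pval for c in calls if c.pval is not None]
        q0s = [c.q0 for c in calls if c.q0 is not None]
        cns = [c.est_cn for c in calls if c.est_cn is not None]
        out.append(
            CnvCall(
                sample_id=calls[0].sample_id,
                caller=CONSENSUS_CALLER,
                chrom=calls[0].chrom,
                start=start,
                end=end,
                svtype=svtype,
                pval=min(pvals) if pvals else None,
                q0=max(q0s) if q0s else None,
                est_cn=float(statistics.fmean(cns)) if cns else None,
            )
        )
    out.sort(key=lambda c: (c.chrom, c.start, c.end, c.svtype))
    return out
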