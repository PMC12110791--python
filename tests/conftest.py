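"""Shared fixtures: simulated cohorts and the analysis chain run over them."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from cnvpop.call_processing import ConsensusPolicy, FilterPolicy, consensus_merge, filter_calls
from cnvpop.cnvr_builder import Cnvr, LengthPolicy, build_cnvrs
from cnvpop.genotyping import CnMatrix, genotype_cnvrs
from cnvpop.synthetic_data import (
    SimConfig,
    SimulatedCohort,
    match_loci_to_cnvrs,
    simulate_cohort,
)


@dataclass
class ChainProducts:
    """Everything the filter -> consensus -> CNVR -> genotype chain yields."""

    cohort: SimulatedCohort
    cnvrs: list[Cnvr]
    matrix: CnMatrix
    locus_to_cnvr: dict[str, str | None]


def run_chain(cohort: SimulatedCohort) -> ChainProducts:
    fp, cp = FilterPolicy(), ConsensusPolicy()
    consensus_calls = []
    for sample in cohort.config.sample_ids:
        per_caller = {k: filter_calls(v, fp) for k, v in cohort.calls[sample].items()}
        consensus_calls.extend(consensus_merge(per_caller, cp))
    cnvrs = build_cnvrs(consensus_calls, LengthPolicy(), cohort.layout)
    matrix = genotype_cnvrs(cnvrs, cohort.depth)
    return ChainProducts(
        cohort=cohort,
        cnvrs=cnvrs,
        matrix=matrix,
        locus_to_cnvr=match_loci_to_cnvrs(cohort.truth, cnvrs),
    )


@pytest.fixture(scope="session")
def default_cohort() -> SimulatedCohort:
    """Study-condition cohort: 7/10/10 samples, 60 shared + 12 divergent loci,
    50 bp jitter, 5% FN, 2% FP, Poisson depth at 30 reads/window."""
    return simulate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_products(default_cohort) -> ChainProducts:
    return run_chain(default_cohort)


@pytest.fixture(scope="session")
def noiseless_cohort() -> SimulatedCohort:
    return simulate_cohort(
        SimConfig(seed=3, jitter_sd=0.0, fn_rate=0.0, fp_rate=0.0, depth_noise=False)
    )


@pytest.fixture(scope="session")
def noiseless_products(noiseless_cohort) -> ChainProducts:
    return run_chain(noiseless_cohort)
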