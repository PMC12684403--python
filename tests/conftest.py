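"""Shared fixtures.

The heavy benchmark dataset (a 20-species community with ~10,000 reads,
spiked with chimeras and concatemers at the default forge settings) is built
once per session and shared by the detector-performance, monotonicity and
simulator-acceptance tests together with one alignment cache, so repeated
detector runs only pay for thresholding, not re-alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from chimbench.bench import score_calls
from chimbench.community import (
    CommunityConfig,
    make_58s_consensus,
    make_templates,
    sample_abundances,
    simulate_reads,
)
from chimbench.detect import AlignmentCache, DetectorParams, detect
from chimbench.forge import ForgeConfig, spike_dataset
from chimbench.records import AmpliconRecord, dereplicate, maxee_filter


@dataclass
class BenchData:
    config: CommunityConfig
    forge_config: ForgeConfig
    templates: list
    consensus: str
    reads: list
    kept: list
    spiked: list
    truth: pd.DataFrame


BENCH_COMMUNITY = CommunityConfig(n_species=20, per_species_reads=(450, 550), seed=7)
BENCH_FORGE = ForgeConfig(seed=8)


@pytest.fixture(scope="session")
def bench_data() -> BenchData:
    cfg = BENCH_COMMUNITY
    templates = make_templates(cfg)
    reads = simulate_reads(templates, sample_abundances(templates, cfg), cfg)
    kept, _ = maxee_filter(reads, 1.0)
    spiked, truth = spike_dataset(kept, templates, BENCH_FORGE)
    return BenchData(
        config=cfg,
        forge_config=BENCH_FORGE,
        templates=templates,
        consensus=make_58s_consensus(cfg),
        reads=reads,
        kept=kept,
        spiked=spiked,
        truth=truth,
    )


@pytest.fixture(scope="session")
def bench_cache() -> AlignmentCache:
    return AlignmentCache()


@pytest.fixture(scope="session")
def bench_calls_default(bench_data, bench_cache):
    return detect(bench_data.spiked, DetectorParams(), cache=bench_cache)


@pytest.fixture(scope="session")
def bench_counts_default(bench_data, bench_calls_default):
    return score_calls(bench_calls_default, bench_data.truth)


@dataclass
class SmallCommunity:
    config: CommunityConfig
    templates: list
    consensus: str
    reads: list
    derep: list
    refs: list
    regions: dict


@pytest.fixture(scope="session")
def small_community() -> SmallCommunity:
    """A 10-species, error-bearing community small enough for full-DP search."""
    cfg = CommunityConfig(n_species=10, per_species_reads=(8, 10), seed=11, low_q_fraction=0.0)
    templates = make_templates(cfg)
    reads = simulate_reads(templates, sample_abundances(templates, cfg), cfg)
    regions = {t.id: t.regions for t in templates}
    read_regions = {r.id: regions[r.source_id] for r in reads}
    derep = dereplicate(reads)
    for r in derep:
        read_regions.setdefault(r.id, regions[r.source_id])
    return SmallCommunity(
        config=cfg,
        templates=templates,
        consensus=make_58s_consensus(cfg),
        reads=reads,
        derep=derep,
        refs=[AmpliconRecord(id=f"ref_{t.id}", seq=t.seq) for t in templates],
        regions=read_regions,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
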