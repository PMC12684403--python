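"""Synthetic full-ITS community: templates, abundance profiles, noisy reads.

Templates follow the rRNA operon layout ITS1-5.8S-ITS2. The 5.8S is a single
community-wide consensus mutated per species at a small fixed divergence (the
conserved anchor that makes concatemer detection by 5.8S multiplicity
meaningful); ITS1/ITS2 are drawn independently per species with uniform base
composition, so inter-species spacer identity is near the ~25% random floor.

Reads are templates passed through an independent per-base error channel
(substitution / insertion / deletion) with PacBio-like per-base qualities: a
HiFi-like high-Q component plus a configurable junk fraction of globally
low-Q reads that exercises maxEE filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .records import AmpliconRecord, TruthClass, TruthLabel, write_fasta

__all__ = [
    "ReferenceTemplate",
    "CommunityConfig",
    "make_templates",
    "sample_abundances",
    "simulate_reads",
    "write_templates",
    "read_region_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class ReferenceTemplate:
    """Species-level ITS1-5.8S-ITS2 template with region coordinates.

    Spans are 0-based half-open, ordered, and tile the sequence exactly.
    """

    id: str
    seq: str
    its1_span: tuple[int, int]
    r58s_span: tuple[int, int]
    its2_span: tuple[int, int]
    taxon: str = ""

    def __post_init__(self):
        spans = (self.its1_span, self.r58s_span, self.its2_span)
        if spans[0][0] != 0 or spans[2][1] != len(self.seq):
            raise ValueError(f"{self.id}: spans must tile the sequence")
        for (a, b), (c, d) in zip(spans, spans[1:]):
            if b != c or a >= b or c >= d:
                raise ValueError(f"{self.id}: spans must be ordered, nonempty and contiguous")

    @property
    def regions(self) -> dict[str, tuple[int, int]]:
        return {"ITS1": self.its1_span, "5.8S": self.r58s_span, "ITS2": self.its2_span}


@dataclass
class CommunityConfig:
    """Study-scale defaults: 186 species, 1,000-9,000 reads each.

    Error rates are per-base, per-pass probabilities of the PacBio-like
    channel. Each read is a circular-consensus of ``passes`` subreads (drawn
    uniformly from ``passes_range``), so its effective error rate is the
    channel rate divided by its pass count — this reproduces the hallmark of
    multi-pass long-read data that a substantial fraction of reads is exactly
    error-free (and therefore dereplicates onto its template).
    ``low_q_fraction`` is the share of reads emitted with globally low quality
    (they fail maxEE = 1 and model the junk the preprocessing step removes).
    """

    n_species: int = 186
    per_species_reads: tuple[int, int] = (1000, 9000)
    p_sub: float = 0.002
    p_ins: float = 0.0025
    p_del: float = 0.0025
    seed: int = 0
    d58: float = 0.03
    r58s_len: int = 157
    its1_range: tuple[int, int] = (120, 400)
    its2_range: tuple[int, int] = (150, 420)
    passes_range: tuple[int, int] = (1, 30)
    low_q_fraction: float = 0.05
    high_q_range: tuple[int, int] = (85, 93)
    err_q_range: tuple[int, int] = (10, 25)
    low_q_range: tuple[int, int] = (2, 12)

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        for p in (self.p_sub, self.p_ins, self.p_del, self.d58, self.low_q_fraction):
            if not 0 <= p < 1:
                raise ValueError("probabilities must be in [0, 1)")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(["A", "C", "G", "T"], size=n))


def make_58s_consensus(config: CommunityConfig) -> str:
    """The community's shared 5.8S consensus (derived from the seed alone)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 58]))
    return _random_seq(rng, config.r58s_len)


def make_templates(config: CommunityConfig) -> list[ReferenceTemplate]:
    """Generate ``n_species`` templates; deterministic under the seed.

    Each species' 5.8S is the consensus with exactly round(d58 * len)
    substitutions at distinct positions, so conservation is guaranteed rather
    than merely expected.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    consensus = make_58s_consensus(config)
    n_mut = int(round(config.d58 * config.r58s_len))
    width = max(3, len(str(config.n_species)))
    templates: list[ReferenceTemplate] = []
    for i in range(config.n_species):
        its1 = _random_seq(rng, int(rng.integers(config.its1_range[0], config.its1_range[1] + 1)))
        its2 = _random_seq(rng, int(rng.integers(config.its2_range[0], config.its2_range[1] + 1)))
        r58 = list(consensus)
        for pos in rng.choice(len(consensus), size=n_mut, replace=False):
            alt = [b for b in "ACGT" if b != r58[pos]]
            r58[pos] = alt[int(rng.integers(3))]
        seq = its1 + "".join(r58) + its2
        a, b = len(its1), len(its1) + config.r58s_len
        templates.append(
            ReferenceTemplate(
                id=f"sp{i + 1:0{width}d}",
                seq=seq,
                its1_span=(0, a),
                r58s_span=(a, b),
                its2_span=(b, len(seq)),
                taxon=f"Species_{i + 1:0{width}d}",
            )
        )
    return templates


def sample_abundances(
    templates: Sequence[ReferenceTemplate], config: CommunityConfig
) -> dict[str, int]:
    """Per-template read counts, uniform over the configured inclusive range."""
    lo, hi = config.per_species_reads
    if lo < 1 or hi < lo:
        raise ValueError("per_species_reads range must satisfy 1 <= lo <= hi")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    return {t.id: int(rng.integers(lo, hi + 1)) for t in templates}


_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _channel(
    seq: str, rng: np.random.Generator, p_sub: float, p_ins: float, p_del: float
) -> tuple[str, np.ndarray]:
    """One pass through the error channel; returns (read, per-base error flags)."""
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)].copy()
    L = len(codes)
    u = rng.random(L)
    del_mask = u < p_del
    sub_mask = (u >= p_del) & (u < p_del + p_sub)
    ins_mask = rng.random(L + 1) < p_ins

    sub_idx = np.flatnonzero(sub_mask)
    if sub_idx.size:  # substitute with one of the three other bases
        codes[sub_idx] = (codes[sub_idx] + rng.integers(1, 4, size=sub_idx.size)) % 4

    keep = ~del_mask
    out = codes[keep]
    err = sub_mask[keep]

    ins_idx = np.flatnonzero(ins_mask)
    if ins_idx.size:
        kept_before = np.concatenate(([0], np.cumsum(keep)))
        pos = kept_before[ins_idx]
        out = np.insert(out, pos, rng.integers(0, 4, size=ins_idx.size).astype(np.uint8))
        err = np.insert(err, pos, True)
    if out.size == 0:  # pathological all-deleted read; emit one random base
        out = rng.integers(0, 4, size=1).astype(np.uint8)
        err = np.ones(1, dtype=bool)
    read = _BASES[out].tobytes().decode()
    return read, err


def simulate_reads(
    templates: Sequence[ReferenceTemplate],
    counts: dict[str, int],
    config: CommunityConfig,
) -> list[AmpliconRecord]:
    """PacBio-like reads for each template; deterministic under the seed.

    Error-free bases get high Phred scores (capped at 93); realized-error bases
    get low-to-mid scores; a ``low_q_fraction`` share of reads is emitted with
    globally low quality so that maxEE = 1 filtering has something to remove.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    by_id = {t.id: t for t in templates}
    reads: list[AmpliconRecord] = []
    hq_lo, hq_hi = config.high_q_range
    eq_lo, eq_hi = config.err_q_range
    lq_lo, lq_hi = config.low_q_range
    for tid in sorted(counts):
        template = by_id[tid]
        n = counts[tid]
        if n < 1:
            raise ValueError(f"read count for {tid} must be positive")
        lo_p, hi_p = config.passes_range
        for j in range(n):
            passes = int(rng.integers(lo_p, hi_p + 1))
            seq, err = _channel(
                template.seq, rng, config.p_sub / passes, config.p_ins / passes, config.p_del / passes
            )
            if rng.random() < config.low_q_fraction:
                quals = rng.integers(lq_lo, lq_hi + 1, size=len(seq))
            else:
                quals = rng.integers(hq_lo, hq_hi + 1, size=len(seq))
                quals[err] = rng.integers(eq_lo, eq_hi + 1, size=int(err.sum()))
            reads.append(
                AmpliconRecord(
                    id=f"{tid}_r{j + 1:05d}",
                    seq=seq,
                    quals=quals.tolist(),
                    sample_id="sim",
                    source_id=tid,
                    truth=TruthLabel(klass=TruthClass.PARENTAL),
                )
            )
    return reads


_REGION_COLS = [
    "template_id",
    "its1_start",
    "its1_end",
    "r58s_start",
    "r58s_end",
    "its2_start",
    "its2_end",
]


def write_templates(templates: Sequence[ReferenceTemplate], fasta_path, regions_path) -> None:
    """Templates as FASTA plus the region-annotation TSV."""
    write_fasta([AmpliconRecord(id=t.id, seq=t.seq) for t in templates], fasta_path)
    rows = [
        {
            "template_id": t.id,
            "its1_start": t.its1_span[0],
            "its1_end": t.its1_span[1],
            "r58s_start": t.r58s_span[0],
            "r58s_end": t.r58s_span[1],
            "its2_start": t.its2_span[0],
            "its2_end": t.its2_span[1],
        }
        for t in templates
    ]
    pd.DataFrame(rows, columns=_REGION_COLS).to_csv(regions_path, sep="\t", index=False)


def read_region_tsv(path) -> dict[str, dict[str, tuple[int, int]]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, tuple[int, int]]] = {}
    for row in df.itertuples(index=False):
        out[str(row.template_id)] = {
            "ITS1": (int(row.its1_start), int(row.its1_end)),
            "5.8S": (int(row.r58s_start), int(row.r58s_end)),
            "ITS2": (int(row.its2_start), int(row.its2_end)),
        }
    return out
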