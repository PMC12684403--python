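"""Plant ground-truth artifacts into a read set.

Two artifact classes are forged:

* PCR chimeras — segments of two (occasionally three) distinct parents joined
  at region-weighted breakpoints, with length and abundance constraints so the
  artifacts do not dominate their parents; a small fraction carries a
  reverse-complemented 3' segment (the failure mode breakpoint detectors miss
  unless they search both strands).
* Concatemers — 2-3 tandem copies of one parental molecule, the library-prep
  (adapter-skip/re-ligation) artifact. They contain multiple complete 5.8S
  copies and no two-parent breakpoint structure, so breakpoint-based
  detectors handle them poorly; the 5.8S-multiplicity scan in
  post-validation is what catches them reliably.

Multi-parent chimeras are built as ``a[:bp_a] + b[bp_b:] (+ c[bp_c:])``: the
first parent contributes a prefix and every later parent a suffix, which makes
each chimera exactly reconstructable from its recorded parents and the
artifact-coordinate breakpoints alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import AmpliconRecord, TruthClass, TruthLabel, dereplicate, revcomp

__all__ = ["ForgeConfig", "ForgeError", "forge_chimera", "forge_concatemer", "spike_dataset", "reconstruct_chimera"]

logger = logging.getLogger(__name__)

REGIONS = ("ITS1", "5.8S", "ITS2")


class ForgeError(RuntimeError):
    """Raised when an artifact cannot be forged under the configured constraints."""


@dataclass
class ForgeConfig:
    """Artifact-planting configuration.

    ``chimera_fraction`` and ``concatemer_fraction`` are fractions of the final
    total read count (abundance-weighted). ``region_weights`` steer which ITS
    region breakpoints fall in; ``length_bounds`` constrain the child/parent
    length ratio. Chimera abundance is drawn uniformly from
    {1 .. floor(min(parent abundances)/2)}, which guarantees an abundance skew
    of at least 2 between each parent and the chimera.
    """

    chimera_fraction: float = 0.062
    region_weights: dict[str, float] = field(
        default_factory=lambda: {"ITS1": 0.4, "5.8S": 0.2, "ITS2": 0.4}
    )
    three_parent_fraction: float = 0.05
    rc_segment_fraction: float = 0.02
    length_bounds: tuple[float, float] = (0.7, 1.1)
    concatemer_fraction: float = 0.005
    concatemer_copies: tuple[int, int] = (2, 3)
    seed: int = 0
    max_attempts: int = 100

    def __post_init__(self):
        for f in (self.chimera_fraction, self.three_parent_fraction, self.rc_segment_fraction, self.concatemer_fraction):
            if not 0 <= f < 1:
                raise ValueError("fractions must be in [0, 1)")
        if not 0 < self.chimera_fraction < 0.5:
            raise ValueError("chimera_fraction must be in (0, 0.5)")
        total = sum(self.region_weights.get(r, 0.0) for r in REGIONS)
        if abs(total - 1.0) > 1e-9 or any(w < 0 for w in self.region_weights.values()):
            raise ValueError("region_weights must be nonnegative and sum to 1")


def _pick_region(rng: np.random.Generator, weights: dict[str, float]) -> str:
    w = np.array([weights.get(r, 0.0) for r in REGIONS], dtype=float)
    return REGIONS[int(rng.choice(3, p=w / w.sum()))]


def _breakpoint_in(rng: np.random.Generator, span: tuple[int, int], seq_len: int) -> int:
    """Uniform position inside the region span, clipped to (0, seq_len)."""
    lo = max(1, span[0])
    hi = min(seq_len - 1, span[1] - 1)
    if hi < lo:
        lo = hi = max(1, min(seq_len - 1, span[0]))
    return int(rng.integers(lo, hi + 1))


def _chimera_abundance(rng: np.random.Generator, parents: Sequence[AmpliconRecord]) -> int:
    cap = min(p.abundance for p in parents) // 2
    if cap < 1:
        raise ForgeError("parents must have abundance >= 2 so the chimera stays rarer")
    return int(rng.integers(1, cap + 1))


def forge_chimera(
    parent_a: AmpliconRecord,
    parent_b: AmpliconRecord,
    regions: dict[str, dict[str, tuple[int, int]]],
    config: ForgeConfig,
    rng: np.random.Generator,
    child_id: str = "chim",
    parent_c: Optional[AmpliconRecord] = None,
) -> AmpliconRecord:
    """Forge one PCR chimera from two (or three) distinct parental records.

    Breakpoints are resampled until the child/parent length ratios fall inside
    ``config.length_bounds`` for every parent; after ``config.max_attempts``
    failures a :class:`ForgeError` is raised so the caller can skip the pair.
    """
    parents = [parent_a, parent_b] + ([parent_c] if parent_c is not None else [])
    ids = [p.id for p in parents]
    if len(set(ids)) != len(ids):
        raise ValueError("parents must be distinct records")
    for p in parents:
        if p.truth is not None and p.truth.klass is not TruthClass.PARENTAL:
            raise ValueError(f"parent {p.id} is not parental-class")
    lo, hi = config.length_bounds
    for _ in range(config.max_attempts):
        bps = []
        for p in parents:
            span = regions[p.id][_pick_region(rng, config.region_weights)]
            bps.append(_breakpoint_in(rng, span, len(p.seq)))
        segments = [parents[0].seq[: bps[0]]] + [p.seq[b:] for p, b in zip(parents[1:], bps[1:])]
        child = "".join(segments)
        if not all(lo <= len(child) / len(p.seq) <= hi for p in parents):
            continue
        rc_flags = [False] * len(segments)
        if rng.random() < config.rc_segment_fraction:
            rc_flags[-1] = True
            segments[-1] = revcomp(segments[-1])
            child = "".join(segments)
        offsets = np.cumsum([len(s) for s in segments[:-1]]).tolist()
        truth = TruthLabel(
            klass=TruthClass.PCR_CHIMERA,
            parent_ids=tuple(ids),
            breakpoints=tuple(offsets),
            rc_segments=tuple(rc_flags),
        )
        return AmpliconRecord(
            id=child_id,
            seq=child,
            abundance=_chimera_abundance(rng, parents),
            sample_id=parents[0].sample_id,
            truth=truth,
        )
    raise ForgeError(
        f"length constraint {config.length_bounds} unsatisfiable for parents "
        f"{ids} in {config.max_attempts} attempts"
    )


def reconstruct_chimera(
    truth: TruthLabel, parents_by_id: dict[str, AmpliconRecord], child_length: int
) -> str:
    """Rebuild a chimera's sequence from truth metadata (self-consistency oracle).

    Segment 1 is a prefix of parent 1 ending at the first artifact breakpoint;
    segment k>1 is the suffix of parent k whose length is the distance to the
    next breakpoint (or to the end of the artifact).
    """
    bounds = [0, *truth.breakpoints, child_length]
    segments = []
    for k, pid in enumerate(truth.parent_ids):
        seg_len = bounds[k + 1] - bounds[k]
        pseq = parents_by_id[pid].seq
        seg = pseq[:seg_len] if k == 0 else pseq[len(pseq) - seg_len :]
        if truth.rc_segments and truth.rc_segments[k]:
            seg = revcomp(seg)
        segments.append(seg)
    return "".join(segments)


def forge_concatemer(
    parents: Sequence[AmpliconRecord],
    config: ForgeConfig,
    rng: np.random.Generator,
    child_id: str = "concat",
) -> AmpliconRecord:
    """Join 2-3 complete parental molecules end-to-end (abundance 1).

    Parents may repeat — tandem copies of one molecule are the typical
    library-prep artifact — so the child carries one complete 5.8S per copy.
    """
    if not 2 <= len(parents) <= 3:
        raise ValueError("a concatemer joins 2-3 parents")
    for p in parents:
        if p.truth is not None and p.truth.klass is not TruthClass.PARENTAL:
            raise ValueError(f"parent {p.id} is not parental-class")
    seq = "".join(p.seq for p in parents)
    offsets = np.cumsum([len(p.seq) for p in parents[:-1]]).tolist()
    truth = TruthLabel(
        klass=TruthClass.CONCATEMER,
        parent_ids=tuple(p.id for p in parents),
        breakpoints=tuple(offsets),
        rc_segments=tuple([False] * len(parents)),
    )
    return AmpliconRecord(id=child_id, seq=seq, abundance=1, sample_id=parents[0].sample_id, truth=truth)


def _read_regions(
    records: Sequence[AmpliconRecord],
    template_regions: dict[str, dict[str, tuple[int, int]]],
) -> dict[str, dict[str, tuple[int, int]]]:
    """Region spans for reads, inherited from their source template and clipped."""
    out = {}
    for r in records:
        if r.source_id is None or r.source_id not in template_regions:
            continue
        spans = template_regions[r.source_id]
        L = len(r.seq)
        out[r.id] = {name: (min(a, L), min(b, L)) for name, (a, b) in spans.items()}
    return out


def spike_dataset(
    reads: Sequence[AmpliconRecord],
    templates,
    config: ForgeConfig,
) -> tuple[list[AmpliconRecord], pd.DataFrame]:
    """Dereplicate parental reads, plant chimeras and concatemers, shuffle.

    Chimera parents are drawn from dereplicated records with abundance >= 2
    (rare sequences cannot parent a detectable chimera); total chimeric
    abundance is steered to round(chimera_fraction x final total) within one
    read. Returns the spiked record list and a truth table covering every
    record id.
    """
    from .records import write_truth_tsv  # local import to avoid cycle at module load

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    for r in reads:
        if r.truth is None or r.truth.klass is not TruthClass.PARENTAL:
            raise ValueError("spike_dataset expects parental reads with truth labels")
    parental = dereplicate(reads)
    eligible = [r for r in parental if r.abundance >= 2]
    if len({r.source_id for r in eligible}) < 2 or len(eligible) < 2:
        raise ValueError("need parental records of at least two species with abundance >= 2")

    template_regions = {t.id: t.regions for t in templates}
    regions = _read_regions(parental, template_regions)

    n_parental = sum(r.abundance for r in parental)
    denom = 1.0 - config.chimera_fraction - config.concatemer_fraction
    total = int(round(n_parental / denom))
    target_chim = int(round(config.chimera_fraction * total))
    target_concat = int(round(config.concatemer_fraction * total))

    seen_seqs = {r.seq for r in parental}
    chimeras: list[AmpliconRecord] = []
    planted = 0
    i = 0
    attempts = 0
    while planted < target_chim:
        attempts += 1
        if attempts > 50 * max(target_chim, 1):
            raise ForgeError("unable to reach the requested chimera fraction")
        k = 3 if rng.random() < config.three_parent_fraction else 2
        picks = rng.choice(len(eligible), size=k, replace=False)
        parents = [eligible[int(j)] for j in picks]
        if any(p.id not in regions for p in parents):
            continue
        # template switching joins different molecules: require distinct species
        if len({p.source_id for p in parents}) != k:
            continue
        i += 1
        try:
            chim = forge_chimera(
                parents[0],
                parents[1],
                regions,
                config,
                rng,
                child_id=f"chimera_{i:05d}",
                parent_c=parents[2] if k == 3 else None,
            )
        except ForgeError as exc:
            logger.info("skipping pair: %s", exc)
            continue
        if chim.seq in seen_seqs:  # keep the spiked set dereplicated
            continue
        seen_seqs.add(chim.seq)
        if planted + chim.abundance > target_chim:
            chim.abundance = target_chim - planted
        planted += chim.abundance
        chimeras.append(chim)

    concatemers: list[AmpliconRecord] = []
    lo_c, hi_c = config.concatemer_copies
    pool = [r for r in parental if r.id in regions]
    j = 0
    attempts = 0
    while len(concatemers) < target_concat:
        attempts += 1
        if attempts > 100 * max(target_concat, 1):
            raise ForgeError("unable to plant the requested concatemer count without duplicates")
        copies = int(rng.integers(lo_c, hi_c + 1))
        parent = pool[int(rng.integers(len(pool)))]
        j += 1
        cat = forge_concatemer([parent] * copies, config, rng, child_id=f"concat_{j:05d}")
        if cat.seq in seen_seqs:
            continue
        seen_seqs.add(cat.seq)
        concatemers.append(cat)

    spiked = list(parental) + chimeras + concatemers
    order = rng.permutation(len(spiked))
    spiked = [spiked[int(k)] for k in order]

    rows = []
    for r in spiked:
        t = r.truth
        rows.append(
            {
                "read_id": r.id,
                "klass": t.klass.value,
                "parent_ids": ",".join(t.parent_ids),
                "breakpoints": ",".join(str(b) for b in t.breakpoints),
                "rc_segments": ",".join("1" if x else "0" for x in t.rc_segments),
                "abundance": r.abundance,
            }
        )
    truth_df = pd.DataFrame(
        rows, columns=["read_id", "klass", "parent_ids", "breakpoints", "rc_segments", "abundance"]
    )
    return spiked, truth_df
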