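"""Core amplicon records, FASTA/FASTQ I/O, dereplication and maxEE filtering.

The on-disk dialect follows the USEARCH/VSEARCH conventions used throughout
long-read metabarcoding pipelines: abundances travel as a trailing ``;size=N``
header annotation, qualities are Phred+33 with the PacBio cap of 93, and
dereplication is exact full-length identity (``--derep_fulllength`` semantics).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TruthClass",
    "TruthLabel",
    "AmpliconRecord",
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "expected_errors",
    "maxee_filter",
    "dereplicate",
    "revcomp",
    "read_truth_tsv",
    "write_truth_tsv",
]

MAX_PHRED = 93  # PacBio dialect cap (vsearch --fastq_qmax 93)

_VALID_BASES = frozenset("ACGTN")
_SIZE_RE = re.compile(r";size=(\d+);?$")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Malformed sequence file content."""


class TruthClass(str, Enum):
    PARENTAL = "parental"
    PCR_CHIMERA = "pcr_chimera"
    CONCATEMER = "concatemer"


@dataclass(frozen=True)
class TruthLabel:
    """Ground-truth provenance of a synthetic read.

    ``breakpoints`` are 0-based positions in the artifact sequence where the
    next segment starts; ``rc_segments`` marks, per segment, whether that
    segment was reverse-complemented before joining.
    """

    klass: TruthClass
    parent_ids: tuple[str, ...] = ()
    breakpoints: tuple[int, ...] = ()
    rc_segments: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        klass = TruthClass(self.klass)
        object.__setattr__(self, "klass", klass)
        object.__setattr__(self, "parent_ids", tuple(self.parent_ids))
        object.__setattr__(self, "breakpoints", tuple(int(b) for b in self.breakpoints))
        object.__setattr__(self, "rc_segments", tuple(bool(b) for b in self.rc_segments))
        if klass is TruthClass.PARENTAL:
            if self.breakpoints:
                raise ValueError("parental truth must not carry breakpoints")
        elif klass is TruthClass.PCR_CHIMERA:
            if not 2 <= len(self.parent_ids) <= 3:
                raise ValueError("pcr_chimera needs 2-3 parents")
            if len(self.breakpoints) != len(self.parent_ids) - 1:
                raise ValueError("pcr_chimera needs len(parents)-1 breakpoints")
        else:  # concatemer
            if len(self.parent_ids) < 2:
                raise ValueError("concatemer needs >=2 parents")
        if any(b2 <= b1 for b1, b2 in zip(self.breakpoints, self.breakpoints[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        if any(b <= 0 for b in self.breakpoints):
            raise ValueError("breakpoints must be > 0")


@dataclass
class AmpliconRecord:
    """One read or dereplicated sequence.

    ``abundance`` carries the ``;size=N`` count; ``source_id`` optionally
    records the template a synthetic read was simulated from.
    """

    id: str
    seq: str
    quals: Optional[list[int]] = None
    abundance: int = 1
    sample_id: Optional[str] = None
    source_id: Optional[str] = None
    truth: Optional[TruthLabel] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be nonempty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.seq = self.seq.upper()
        bad = set(self.seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid characters {sorted(bad)} (alphabet is A,C,G,T,N)"
            )
        if self.abundance < 1:
            raise ValueError(f"record {self.id!r}: abundance must be >= 1")
        if self.quals is not None:
            self.quals = [int(q) for q in self.quals]
            if len(self.quals) != len(self.seq):
                raise ValueError(
                    f"record {self.id!r}: {len(self.quals)} quality scores for "
                    f"{len(self.seq)} bases"
                )
            if any(q < 0 or q > MAX_PHRED for q in self.quals):
                raise ValueError(f"record {self.id!r}: Phred scores must be in [0, {MAX_PHRED}]")

    def __len__(self) -> int:
        return len(self.seq)

    def copy(self, **changes) -> "AmpliconRecord":
        return replace(self, **changes)


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution by construction."""
    bad = set(seq.upper()) - _VALID_BASES
    if bad:
        raise ValueError(f"invalid characters for revcomp: {sorted(bad)}")
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _strip_size(header_id: str, parse_size: bool) -> tuple[str, int]:
    if not parse_size:
        return header_id, 1
    m = _SIZE_RE.search(header_id)
    if m is None:
        return header_id, 1
    return header_id[: m.start()], int(m.group(1))


def _check_unique(ids: Iterable[str]) -> None:
    seen: set[str] = set()
    for rid in ids:
        if rid in seen:
            raise ParseError(f"duplicate record id {rid!r}")
        seen.add(rid)


def read_fasta(path, parse_size: bool = False) -> list[AmpliconRecord]:
    """Read FASTA; with ``parse_size`` a trailing ``;size=N`` sets abundance."""
    path = Path(path)
    records: list[AmpliconRecord] = []
    line_no = 0
    with path.open() as fh:
        header_line = {}
        # Track header line numbers so parse errors can point at them.
        for i, line in enumerate(fh, 1):
            if line.startswith(">"):
                header_line[line[1:].split()[0] if line[1:].split() else ""] = i
    for rec in SeqIO.parse(str(path), "fasta"):
        line_no = header_line.get(rec.id, 0)
        if not rec.id:
            raise ParseError(f"{path}: malformed header at line {line_no}")
        if len(rec.seq) == 0:
            raise ParseError(f"{path}: empty sequence for {rec.id!r} (header at line {line_no})")
        rid, size = _strip_size(rec.id, parse_size)
        try:
            records.append(AmpliconRecord(id=rid, seq=str(rec.seq), abundance=size))
        except ValueError as exc:
            raise ParseError(f"{path} (header at line {line_no}): {exc}") from exc
    _check_unique(r.id for r in records)
    return records


def write_fasta(records: Sequence[AmpliconRecord], path, with_size: bool = False) -> None:
    path = Path(path)
    seqs = []
    for r in records:
        rid = f"{r.id};size={r.abundance}" if with_size else r.id
        seqs.append(SeqRecord(Seq(r.seq), id=rid, description=""))
    with path.open("w") as fh:
        SeqIO.write(seqs, fh, "fasta-2line")


def read_fastq(path) -> list[AmpliconRecord]:
    """Read Phred+33 FASTQ; scores above 93 are clamped with a warning."""
    path = Path(path)
    records: list[AmpliconRecord] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
        quals = rec.letter_annotations["phred_quality"]
        if any(q > MAX_PHRED for q in quals):
            warnings.warn(
                f"{path}: record {rec.id!r} has Phred scores > {MAX_PHRED}; clamping",
                stacklevel=2,
            )
            quals = [min(q, MAX_PHRED) for q in quals]
        if len(rec.seq) == 0:
            raise ParseError(f"{path}: empty sequence for record {i + 1} ({rec.id!r})")
        try:
            records.append(AmpliconRecord(id=rec.id, seq=str(rec.seq), quals=list(quals)))
        except ValueError as exc:
            raise ParseError(f"{path}: record {i + 1} ({rec.id!r}): {exc}") from exc
    _check_unique(r.id for r in records)
    return records


def write_fastq(records: Sequence[AmpliconRecord], path) -> None:
    path = Path(path)
    seqs = []
    for r in records:
        if r.quals is None:
            raise ValueError(f"record {r.id!r} has no qualities; cannot write FASTQ")
        s = SeqRecord(Seq(r.seq), id=r.id, description="")
        s.letter_annotations["phred_quality"] = list(r.quals)
        seqs.append(s)
    with path.open("w") as fh:
        SeqIO.write(seqs, fh, "fastq")


def expected_errors(record: AmpliconRecord) -> float:
    """Expected number of errors, sum over bases of 10^(-Q/10)."""
    if record.quals is None:
        raise ValueError(f"record {record.id!r} has no qualities")
    q = np.asarray(record.quals, dtype=float)
    return float(np.sum(10.0 ** (-q / 10.0)))


def maxee_filter(
    records: Sequence[AmpliconRecord], maxee: float
) -> tuple[list[AmpliconRecord], list[AmpliconRecord]]:
    """Partition records into (kept, discarded) by EE <= maxee (inclusive).

    A tiny relative tolerance keeps the inclusive boundary stable against
    floating-point summation (100 bases at Q20 is exactly EE = 1).
    """
    kept: list[AmpliconRecord] = []
    discarded: list[AmpliconRecord] = []
    thr = maxee * (1.0 + 1e-9) + 1e-12
    for r in records:
        (kept if expected_errors(r) <= thr else discarded).append(r)
    return kept, discarded


def dereplicate(records: Sequence[AmpliconRecord]) -> list[AmpliconRecord]:
    """Collapse exact full-length duplicates, summing abundances.

    The representative is the highest-abundance member (ties: lexicographically
    smallest id); output is sorted by abundance descending, ties by id.
    Qualities are dropped (dereplicated sets are abundance-annotated FASTA).
    """
    groups: dict[str, list[AmpliconRecord]] = {}
    for r in records:
        groups.setdefault(r.seq, []).append(r)
    out: list[AmpliconRecord] = []
    for seq, members in groups.items():
        rep = min(members, key=lambda r: (-r.abundance, r.id))
        total = sum(r.abundance for r in members)
        out.append(rep.copy(quals=None, abundance=total))
    out.sort(key=lambda r: (-r.abundance, r.id))
    return out


# --- truth-label sidecar TSV -------------------------------------------------

_TRUTH_COLS = ["read_id", "klass", "parent_ids", "breakpoints", "rc_segments"]


def write_truth_tsv(records: Sequence[AmpliconRecord], path) -> pd.DataFrame:
    """Serialize per-read truth labels; returns the DataFrame written."""
    rows = []
    for r in records:
        if r.truth is None:
            raise ValueError(f"record {r.id!r} has no truth label")
        t = r.truth
        rows.append(
            {
                "read_id": r.id,
                "klass": t.klass.value,
                "parent_ids": ",".join(t.parent_ids),
                "breakpoints": ",".join(str(b) for b in t.breakpoints),
                "rc_segments": ",".join("1" if x else "0" for x in t.rc_segments),
            }
        )
    df = pd.DataFrame(rows, columns=_TRUTH_COLS)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_truth_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_TRUTH_COLS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: truth TSV missing columns {sorted(missing)}")
    return df


def truth_from_row(row) -> TruthLabel:
    """Rebuild a TruthLabel from one truth-TSV row."""
    parents = tuple(p for p in str(row["parent_ids"]).split(",") if p)
    bps = tuple(int(b) for b in str(row["breakpoints"]).split(",") if b)
    rcs = tuple(x == "1" for x in str(row["rc_segments"]).split(",") if x)
    return TruthLabel(klass=TruthClass(row["klass"]), parent_ids=parents, breakpoints=bps, rc_segments=rcs)
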