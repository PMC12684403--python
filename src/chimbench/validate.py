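"""Secondary validation of chimera-filter output against reference databases.

Three rules, applied after de novo filtering:

* **False-positive rescue** — a flagged read whose best reference alignment
  reaches >= 99% identity at >= 99% query coverage is a genuine biological
  sequence that was wrongly discarded; everything else in the flagged set is
  confirmed chimeric.
* **False-negative flagging** — a retained read whose best non-self hit
  (against the sample's own reads plus the reference set) splits into
  multiple HSPs with the top-scoring HSP covering < 85% of the query is a
  chimera that slipped through.
* **5.8S multiplicity** — a genuine full-ITS amplicon contains exactly one
  5.8S gene; two or more non-overlapping 5.8S hits mark a concatemer.

Query coverage for the rescue rule comes from a semi-global alignment (query
end-to-end, free target overhangs), so identity carries the signal; "first
HSP" means the highest-scoring HSP. The 5.8S scan uses consensus local
alignment against a user-supplied (or community) 5.8S model sequence rather
than a covariance-model search; for synthetic communities the consensus *is*
the generative model, for real data supply a curated 5.8S sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .align import AlignmentHit, ScoringParams, align_semiglobal, best_hit, find_hsps
from .records import AmpliconRecord

__all__ = [
    "ValidationConfig",
    "ValidationVerdict",
    "rescue_false_positives",
    "flag_false_negatives",
    "count_58s",
    "fn_structure_report",
    "FnStructureReport",
    "verdicts_to_tsv",
]

logger = logging.getLogger(__name__)


@dataclass
class ValidationConfig:
    """Thresholds of the validation rules (all inclusive as documented).

    ``id_min_pct``/``cov_min_pct`` — the >= 99/99 rescue rule.
    ``hsp_cov_max_pct`` — the strict < 85% first-HSP coverage rule.
    ``r58s_model`` — 5.8S consensus sequence for the multiplicity scan.
    ``r58s_id_min_pct``/``r58s_cov_min_frac`` — acceptance thresholds for one
    5.8S hit (identity over alignment columns; fraction of the model aligned).
    ``prescreen`` — shared-k-mer pre-ranking depth for the false-negative
    database search (the full dynamic-programming scan only runs on that many
    best-sharing targets).
    """

    id_min_pct: float = 99.0
    cov_min_pct: float = 99.0
    hsp_cov_max_pct: float = 85.0
    min_hsps_for_fn: int = 2
    r58s_model: Optional[str] = None
    r58s_id_min_pct: float = 85.0
    r58s_cov_min_frac: float = 0.8
    prescreen: int = 10
    scoring: ScoringParams = field(default_factory=ScoringParams)

    def __post_init__(self):
        for pct in (self.id_min_pct, self.cov_min_pct, self.hsp_cov_max_pct, self.r58s_id_min_pct):
            if not 0 < pct <= 100:
                raise ValueError("percent thresholds must be in (0, 100]")


@dataclass
class ValidationVerdict:
    read_id: str
    verdict: str  # fp_rescued | true_chimera | fn_chimera | non_chimera
    best_target: Optional[str] = None
    identity_pct: float = 0.0
    coverage_pct: float = 0.0
    n_hsps: int = 0
    first_hsp_cov_pct: float = 0.0
    n_58s: int = -1
    length: int = 0


def rescue_false_positives(
    flagged: Sequence[AmpliconRecord],
    reference_db: Sequence[AmpliconRecord],
    config: ValidationConfig = ValidationConfig(),
) -> dict[str, ValidationVerdict]:
    """Classify each flagged read as fp_rescued or true_chimera.

    Thresholds are inclusive: identity exactly 99.0% at full coverage rescues.
    """
    if not reference_db:
        raise ValueError("reference database is empty")
    out: dict[str, ValidationVerdict] = {}
    for read in flagged:
        best: Optional[AlignmentHit] = None
        for ref in reference_db:
            hit = align_semiglobal(read.seq, ref.seq, config.scoring, query_id=read.id, target_id=ref.id)
            if best is None or (
                (-hit.best_identity_pct, hit.target_id) < (-best.best_identity_pct, best.target_id)
            ):
                best = hit
        ident = best.best_identity_pct
        cov = best.query_coverage_pct
        rescued = ident >= config.id_min_pct and cov >= config.cov_min_pct
        out[read.id] = ValidationVerdict(
            read_id=read.id,
            verdict="fp_rescued" if rescued else "true_chimera",
            best_target=best.target_id,
            identity_pct=ident,
            coverage_pct=cov,
            n_hsps=len(best.hsps),
            first_hsp_cov_pct=best.hsps[0].query_coverage_pct(len(read.seq)),
            length=len(read.seq),
        )
    return out


def flag_false_negatives(
    retained: Sequence[AmpliconRecord],
    sample_db: Sequence[AmpliconRecord],
    reference_db: Sequence[AmpliconRecord],
    config: ValidationConfig = ValidationConfig(),
) -> dict[str, ValidationVerdict]:
    """Flag retained reads whose best non-self hit betrays chimeric structure.

    The database is the sample's own reads plus the references, searched in
    one pass with self-hits excluded by id. A read is ``fn_chimera`` when the
    best hit has >= ``min_hsps_for_fn`` HSPs and its highest-scoring HSP
    covers < ``hsp_cov_max_pct`` of the query; otherwise ``non_chimera``.
    """
    db = list(sample_db) + [r for r in reference_db if r.id not in {s.id for s in sample_db}]
    out: dict[str, ValidationVerdict] = {}
    for read in retained:
        hit = best_hit(read, db, params=config.scoring, exclude_self=True, prescreen=config.prescreen)
        if hit is None or not hit.hsps:
            logger.info("no non-self hit for %s; keeping as non_chimera", read.id)
            out[read.id] = ValidationVerdict(read_id=read.id, verdict="non_chimera", length=len(read.seq))
            continue
        first = hit.first_hsp
        first_cov = first.query_coverage_pct(len(read.seq))
        is_fn = len(hit.hsps) >= config.min_hsps_for_fn and first_cov < config.hsp_cov_max_pct
        out[read.id] = ValidationVerdict(
            read_id=read.id,
            verdict="fn_chimera" if is_fn else "non_chimera",
            best_target=hit.target_id,
            identity_pct=hit.best_identity_pct,
            coverage_pct=hit.query_coverage_pct,
            n_hsps=len(hit.hsps),
            first_hsp_cov_pct=first_cov,
            length=len(read.seq),
        )
    return out


def count_58s(read: AmpliconRecord, config: ValidationConfig) -> int:
    """Number of non-overlapping 5.8S model hits in the read.

    Greedy by score with read-interval masking: each accepted hit must reach
    ``r58s_id_min_pct`` identity and align at least ``r58s_cov_min_frac`` of
    the model. A genuine amplicon yields 1; concatemers yield one per copy.
    """
    if not config.r58s_model:
        raise ValueError("ValidationConfig.r58s_model is not set")
    model = config.r58s_model.upper()
    min_model_cols = config.r58s_cov_min_frac * len(model)
    # The read is the masked side (hits must not overlap on the read); the
    # model is the target, so t-coordinates measure model coverage.
    hit = find_hsps(
        read.seq,
        model,
        params=config.scoring,
        max_hsps=max(2, len(read.seq) // max(1, int(min_model_cols)) + 1),
        min_hsp_score=10,
        both_strands=False,
    )
    count = 0
    for h in hit.hsps:
        model_cov = h.t_end - h.t_start
        if h.identity_pct >= config.r58s_id_min_pct and model_cov >= min_model_cols:
            count += 1
    return count


@dataclass
class FnStructureReport:
    """5.8S-multiplicity structure of a false-negative read set."""

    per_read: pd.DataFrame  # read_id, length, n_58s
    n_reads: int
    n_multi_58s: int
    multi_fraction: float
    median_len_multi: float
    median_len_single: float


def fn_structure_report(
    fn_reads: Sequence[AmpliconRecord],
    n_58s: dict[str, int],
) -> FnStructureReport:
    """Summarize 5.8S multiplicity and length for a false-negative set.

    ``n_58s`` maps read id to its 5.8S count (from :func:`count_58s`).
    """
    rows = [
        {"read_id": r.id, "length": len(r.seq), "n_58s": int(n_58s[r.id])} for r in fn_reads
    ]
    df = pd.DataFrame(rows, columns=["read_id", "length", "n_58s"])
    if df.empty:
        return FnStructureReport(df, 0, 0, float("nan"), float("nan"), float("nan"))
    multi = df["n_58s"] >= 2
    return FnStructureReport(
        per_read=df,
        n_reads=len(df),
        n_multi_58s=int(multi.sum()),
        multi_fraction=float(multi.mean()),
        median_len_multi=float(df.loc[multi, "length"].median()) if multi.any() else float("nan"),
        median_len_single=float(df.loc[~multi, "length"].median()) if (~multi).any() else float("nan"),
    )


def verdicts_to_tsv(verdicts: dict[str, ValidationVerdict], path) -> pd.DataFrame:
    rows = [
        {
            "read_id": v.read_id,
            "verdict": v.verdict,
            "best_target": v.best_target or "",
            "identity_pct": round(v.identity_pct, 3),
            "coverage_pct": round(v.coverage_pct, 3),
            "n_hsps": v.n_hsps,
            "first_hsp_cov_pct": round(v.first_hsp_cov_pct, 3),
            "n_58s": v.n_58s,
            "length": v.length,
        }
        for v in verdicts.values()
    ]
    df = pd.DataFrame(
        rows,
        columns=["read_id", "verdict", "best_target", "identity_pct", "coverage_pct", "n_hsps", "first_hsp_cov_pct", "n_58s", "length"],
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
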