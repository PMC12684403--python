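"""Scoring arithmetic, degenerate conventions, sweeps and best-run selection."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chimbench.bench import (
    ConfusionCounts,
    SweepRow,
    chimeras_denovo_sweep_grid,
    run_sweep,
    score_calls,
    select_best,
    sweep_to_tsv,
    uchime_sweep_grid,
)
from chimbench.detect import ChimeraCall, DetectorParams, detect
from chimbench.records import AmpliconRecord


def make_fixture(tp, fp, fn, tn, borderline_tp=0):
    """Calls + truth realizing a given confusion matrix (weight 1 per read)."""
    calls, rows = [], []
    i = 0

    def add(verdict, klass):
        nonlocal i
        rid = f"r{i:06d}"
        i += 1
        parents = ("x", "y") if verdict in ("chimera", "borderline") else ()
        calls.append(ChimeraCall(query_id=rid, verdict=verdict, parents=parents))
        rows.append({"read_id": rid, "klass": klass})

    for _ in range(tp - borderline_tp):
        add("chimera", "pcr_chimera")
    for _ in range(borderline_tp):
        add("borderline", "pcr_chimera")
    for _ in range(fp):
        add("chimera", "parental")
    for _ in range(fn):
        add("clean", "pcr_chimera")
    for _ in range(tn):
        add("clean", "parental")
    return calls, pd.DataFrame(rows)


class TestScoreCalls:
    def test_counts_and_metrics_match_bruteforce_recount(self, rng):
        tp, fp, fn, tn = 37, 11, 13, 200
        calls, truth = make_fixture(tp, fp, fn, tn, borderline_tp=5)
        counts = score_calls(calls, truth)
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (tp, fp, fn, tn)
        assert counts.precision == pytest.approx(tp / (tp + fp))
        assert counts.recall == pytest.approx(tp / (tp + fn))
        p, r = counts.precision, counts.recall
        assert counts.f1 == pytest.approx(2 * p * r / (p + r))

    def test_borderline_flag(self):
        calls, truth = make_fixture(10, 0, 5, 50, borderline_tp=4)
        strict = score_calls(calls, truth, borderline_as_chimera=False)
        assert (strict.tp, strict.fn) == (6, 9)

    def test_degenerate_no_positive_truth_no_calls(self):
        calls, truth = make_fixture(0, 0, 0, 25)
        counts = score_calls(calls, truth)
        assert (counts.precision, counts.recall, counts.f1) == (1.0, 1.0, 1.0)

    def test_degenerate_no_predicted_positive(self):
        calls, truth = make_fixture(0, 0, 10, 25)
        counts = score_calls(calls, truth)
        assert counts.precision == 0.0
        assert counts.recall == 0.0
        assert counts.f1 == 0.0

    def test_missing_truth_row_is_error(self):
        calls, truth = make_fixture(1, 0, 0, 1)
        with pytest.raises(KeyError):
            score_calls(calls, truth.iloc[:1])

    def test_abundance_weighted_counts(self):
        calls = [
            ChimeraCall(query_id="a", verdict="chimera", parents=("x", "y")),
            ChimeraCall(query_id="b", verdict="clean"),
        ]
        truth = pd.DataFrame(
            [
                {"read_id": "a", "klass": "pcr_chimera", "abundance": 7},
                {"read_id": "b", "klass": "parental", "abundance": 3},
            ]
        )
        counts = score_calls(calls, truth)
        assert (counts.tp, counts.tn) == (7, 3)
        assert counts.total == 10

    def test_per_class_recall_and_concatemer_toggle(self):
        calls = [
            ChimeraCall(query_id="c1", verdict="chimera", parents=("x", "y")),
            ChimeraCall(query_id="k1", verdict="clean"),
        ]
        truth = pd.DataFrame(
            [
                {"read_id": "c1", "klass": "pcr_chimera"},
                {"read_id": "k1", "klass": "concatemer"},
            ]
        )
        counts = score_calls(calls, truth)
        assert counts.recall_by_class == {"pcr_chimera": 1.0, "concatemer": 0.0}
        assert (counts.tp, counts.fn) == (1, 1)
        no_cat = score_calls(calls, truth, include_concatemers=False)
        assert (no_cat.tp, no_cat.fn, no_cat.tn) == (1, 0, 1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
    def test_f1_bounded_by_twice_min_side(self, tp, fp, fn, tn):
        counts = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
        assert 0.0 <= counts.f1 <= 1.0
        assert counts.f1 <= 2 * min(counts.precision, counts.recall) + 1e-12


class TestSelectBest:
    def _row(self, f1_target, precision, n_changes=0):
        # build counts hitting approximately the requested precision/f1
        params = DetectorParams() if n_changes == 0 else DetectorParams(minh=0.1)
        tp = 100
        fp = int(round(tp / precision)) - tp if precision > 0 else 10**6
        # choose fn to hit f1: f1 = 2tp / (2tp + fp + fn)
        fn = max(0, int(round(2 * tp / f1_target - 2 * tp - fp)))
        return SweepRow(params=params, counts=ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=1000))

    def test_argmax_f1(self):
        rows = [self._row(0.5, 0.9), self._row(0.9, 0.9), self._row(0.7, 0.9)]
        assert select_best(rows) is rows[1]

    def test_tie_broken_by_precision_then_default_count(self):
        a = SweepRow(DetectorParams(minh=0.1), ConfusionCounts(tp=80, fp=20, fn=20, tn=100))
        b = SweepRow(DetectorParams(), ConfusionCounts(tp=80, fp=20, fn=20, tn=100))
        assert select_best([a, b]) is b  # same f1/precision, fewer non-defaults
        # precision/recall swapped -> bit-identical F1, different precision
        hi_p = SweepRow(DetectorParams(minh=0.2), ConfusionCounts(tp=90, fp=10, fn=35, tn=100))
        lo_p = SweepRow(DetectorParams(minh=0.3), ConfusionCounts(tp=90, fp=35, fn=10, tn=100))
        assert hi_p.counts.f1 == lo_p.counts.f1
        assert select_best([lo_p, hi_p]) is hi_p

    def test_matches_exhaustive_scan(self, rng):
        rows = []
        for _ in range(30):
            tp, fp, fn = (int(x) for x in rng.integers(1, 200, size=3))
            rows.append(SweepRow(DetectorParams(), ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=100)))
        best = select_best(rows)
        assert best.counts.f1 == max(r.counts.f1 for r in rows)

    def test_empty_rows_rejected(self):
        with pytest.raises(ValueError):
            select_best([])


class TestSweep:
    def test_grid_presets_have_published_run_counts(self):
        assert len(uchime_sweep_grid()) == 49
        assert len(chimeras_denovo_sweep_grid()) == 22
        # the winning combinations of each family are present
        assert any(p.abskew == 3.0 and p.minh == 0.09 for p in uchime_sweep_grid())
        assert any(
            p.abskew == 4.0 and p.min_segment_len == 30 and p.max_diff_pct == 0.9
            for p in chimeras_denovo_sweep_grid()
        )

    def test_single_point_sweep_equals_direct_detect(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=300))
        b = "".join(rng.choice(list("ACGT"), size=300))
        records = [
            AmpliconRecord(id="A", seq=a, abundance=10),
            AmpliconRecord(id="B", seq=b, abundance=10),
            AmpliconRecord(id="Q", seq=a[:150] + b[150:], abundance=1),
        ]
        truth = pd.DataFrame(
            [
                {"read_id": "A", "klass": "parental"},
                {"read_id": "B", "klass": "parental"},
                {"read_id": "Q", "klass": "pcr_chimera"},
            ]
        )
        params = DetectorParams()
        rows = run_sweep(records, [params], truth)
        direct = score_calls(detect(records, params), truth)
        assert rows[0].counts == ConfusionCounts(
            tp=direct.tp, fp=direct.fp, fn=direct.fn, tn=direct.tn
        )

    def test_sweep_tsv_has_params_and_metrics(self, tmp_path):
        rows = [SweepRow(DetectorParams(), ConfusionCounts(tp=1, fp=0, fn=1, tn=2))]
        df = sweep_to_tsv(rows, tmp_path / "sweep.tsv")
        assert {"abskew", "minh", "tp", "fp", "fn", "tn", "precision", "recall", "f1"} <= set(df.columns)
        assert len(df) == 1

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            run_sweep([], [], pd.DataFrame())
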