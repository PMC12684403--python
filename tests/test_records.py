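"""Record model, I/O dialects, quality filtering and dereplication."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chimbench.records import (
    AmpliconRecord,
    ParseError,
    TruthClass,
    TruthLabel,
    dereplicate,
    expected_errors,
    maxee_filter,
    read_fasta,
    read_fastq,
    read_truth_tsv,
    revcomp,
    truth_from_row,
    write_fasta,
    write_fastq,
    write_truth_tsv,
)

dna = st.text(alphabet="ACGTN", min_size=1, max_size=80)
ids = st.from_regex(r"[A-Za-z][A-Za-z0-9_.-]{0,12}", fullmatch=True)


class TestRecordModel:
    def test_rejects_bad_alphabet_and_lowercases(self):
        r = AmpliconRecord(id="a", seq="acgtn")
        assert r.seq == "ACGTN"
        with pytest.raises(ValueError, match="invalid characters"):
            AmpliconRecord(id="a", seq="ACGU")

    def test_quality_invariants(self):
        with pytest.raises(ValueError, match="quality scores"):
            AmpliconRecord(id="a", seq="ACGT", quals=[40, 40])
        with pytest.raises(ValueError, match="Phred"):
            AmpliconRecord(id="a", seq="AC", quals=[40, 94])
        with pytest.raises(ValueError, match="abundance"):
            AmpliconRecord(id="a", seq="AC", abundance=0)

    @pytest.mark.parametrize(
        "klass,parents,bps,ok",
        [
            (TruthClass.PARENTAL, (), (), True),
            (TruthClass.PARENTAL, (), (3,), False),
            (TruthClass.PCR_CHIMERA, ("a", "b"), (10,), True),
            (TruthClass.PCR_CHIMERA, ("a", "b"), (), False),
            (TruthClass.PCR_CHIMERA, ("a", "b", "c"), (10, 5), False),  # not increasing
            (TruthClass.CONCATEMER, ("a",), (), False),
            (TruthClass.CONCATEMER, ("a", "a"), (600,), True),
        ],
    )
    def test_truth_label_invariants(self, klass, parents, bps, ok):
        if ok:
            TruthLabel(klass=klass, parent_ids=parents, breakpoints=bps)
        else:
            with pytest.raises(ValueError):
                TruthLabel(klass=klass, parent_ids=parents, breakpoints=bps)


class TestFastaDialect:
    def test_size_annotation_parsed_and_stripped(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">s1;size=3\nACGT\n>s2\nGGTT\n")
        recs = read_fasta(p, parse_size=True)
        assert [(r.id, r.abundance, r.seq) for r in recs] == [("s1", 3, "ACGT"), ("s2", 1, "GGTT")]
        # opt-in: without parse_size the annotation stays in the id
        recs2 = read_fasta(p, parse_size=False)
        assert recs2[0].id == "s1;size=3" and recs2[0].abundance == 1

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">a\nACGT\n>a\nGGTT\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_fasta(p)

    def test_empty_sequence_names_line(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">a\nACGT\n>broken\n>b\nGG\n")
        with pytest.raises(ParseError, match="line 3"):
            read_fasta(p)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(items=st.lists(st.tuples(ids, dna, st.integers(1, 99)), min_size=0, max_size=8, unique_by=lambda t: t[0]))
    def test_roundtrip(self, items, tmp_path_factory):
        path = tmp_path_factory.mktemp("fa") / "r.fasta"
        records = [AmpliconRecord(id=i, seq=s, abundance=a) for i, s, a in items]
        write_fasta(records, path, with_size=True)
        back = read_fasta(path, parse_size=True)
        assert [(r.id, r.seq, r.abundance) for r in back] == [
            (r.id, r.seq, r.abundance) for r in records
        ]


class TestFastq:
    def test_phred33_encoding(self, tmp_path):
        p = tmp_path / "x.fastq"
        p.write_text("@r1\nAC\n+\nI~\n")
        (rec,) = read_fastq(p)
        assert rec.quals == [40, 93]

    def test_length_mismatch_is_parse_error(self, tmp_path):
        p = tmp_path / "x.fastq"
        p.write_text("@r1\nACGT\n+\nII\n")
        with pytest.raises(Exception):
            read_fastq(p)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        items=st.lists(
            st.tuples(ids, st.text(alphabet="ACGTN", min_size=1, max_size=40)),
            min_size=1,
            max_size=6,
            unique_by=lambda t: t[0],
        ),
        rnd=st.randoms(use_true_random=False),
    )
    def test_roundtrip(self, items, rnd, tmp_path_factory):
        path = tmp_path_factory.mktemp("fq") / "r.fastq"
        records = [
            AmpliconRecord(id=i, seq=s, quals=[rnd.randint(0, 93) for _ in s]) for i, s in items
        ]
        write_fastq(records, path)
        back = read_fastq(path)
        assert [(r.id, r.seq, r.quals) for r in back] == [(r.id, r.seq, r.quals) for r in records]


class TestExpectedErrors:
    def test_closed_forms(self):
        assert expected_errors(AmpliconRecord(id="a", seq="A" * 100, quals=[20] * 100)) == pytest.approx(1.0)
        assert expected_errors(AmpliconRecord(id="a", seq="A", quals=[10])) == pytest.approx(0.1)
        with pytest.raises(ValueError):
            expected_errors(AmpliconRecord(id="a", seq="A"))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 93), min_size=1, max_size=60))
    def test_matches_per_base_sum(self, quals):
        rec = AmpliconRecord(id="a", seq="A" * len(quals), quals=quals)
        brute = sum(10.0 ** (-q / 10.0) for q in quals)
        assert expected_errors(rec) == pytest.approx(brute, rel=1e-12)


class TestMaxeeFilter:
    def test_inclusive_boundary(self):
        at_limit = AmpliconRecord(id="a", seq="A" * 100, quals=[20] * 100)  # EE = 1.0
        over = AmpliconRecord(id="b", seq="A" * 101, quals=[20] * 101)  # EE = 1.01
        kept, discarded = maxee_filter([at_limit, over], 1.0)
        assert [r.id for r in kept] == ["a"]
        assert [r.id for r in discarded] == ["b"]

    def test_partition_matches_bruteforce(self, rng):
        records = [
            AmpliconRecord(id=f"r{i}", seq="A" * 50, quals=rng.integers(0, 94, size=50).tolist())
            for i in range(50)
        ]
        kept, discarded = maxee_filter(records, 0.5)
        assert len(kept) + len(discarded) == 50
        assert {r.id for r in kept} | {r.id for r in discarded} == {r.id for r in records}
        brute_kept = sum(1 for r in records if expected_errors(r) <= 0.5 + 1e-9)
        assert len(kept) == brute_kept
        # order preserved within each partition
        order = {r.id: i for i, r in enumerate(records)}
        assert [order[r.id] for r in kept] == sorted(order[r.id] for r in kept)


class TestDereplicate:
    def test_collapses_exact_duplicates(self):
        records = [
            AmpliconRecord(id="x", seq="ACGT"),
            AmpliconRecord(id="y", seq="ACGT", abundance=1),
            AmpliconRecord(id="z", seq="ACGT"),
            AmpliconRecord(id="w", seq="GGTT"),
        ]
        out = dereplicate(records)
        assert [(r.seq, r.abundance) for r in out] == [("ACGT", 3), ("GGTT", 1)]
        assert out[0].id == "x"  # tie on abundance -> lexicographically smallest id

    def test_group_counts_match_hash_oracle(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=6)) for _ in range(120)]
        records = [
            AmpliconRecord(id=f"r{i:03d}", seq=s, abundance=int(rng.integers(1, 5)))
            for i, s in enumerate(seqs)
        ]
        out = dereplicate(records)
        oracle = Counter()
        for r in records:
            oracle[r.seq] += r.abundance
        assert {r.seq: r.abundance for r in out} == dict(oracle)
        assert sum(r.abundance for r in out) == sum(r.abundance for r in records)
        assert len(out) <= len(records)
        assert [(-r.abundance, r.id) for r in out] == sorted((-r.abundance, r.id) for r in out)


class TestRevcomp:
    @pytest.mark.parametrize("seq,expected", [("ACGT", "ACGT"), ("AAAC", "GTTT"), ("NAT", "ATN")])
    def test_examples(self, seq, expected):
        assert revcomp(seq) == expected

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(dna)
    def test_involution(self, seq):
        assert revcomp(revcomp(seq)) == seq

    def test_invalid_character(self):
        with pytest.raises(ValueError):
            revcomp("ACGU")


class TestTruthTsv:
    def test_roundtrip(self, tmp_path):
        records = [
            AmpliconRecord(id="p", seq="ACGT", truth=TruthLabel(klass=TruthClass.PARENTAL)),
            AmpliconRecord(
                id="c",
                seq="ACGTACGT",
                truth=TruthLabel(
                    klass=TruthClass.PCR_CHIMERA,
                    parent_ids=("p", "q"),
                    breakpoints=(4,),
                    rc_segments=(False, True),
                ),
            ),
        ]
        path = tmp_path / "truth.tsv"
        write_truth_tsv(records, path)
        df = read_truth_tsv(path)
        assert list(df["read_id"]) == ["p", "c"]
        label = truth_from_row(df.iloc[1])
        assert label == records[1].truth
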