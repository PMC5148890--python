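from __future__ import annotations

import pytest
from hypothesis import given, strategies as st

from txconsensus.metrics import (
    HitRecord,
    annotatability,
    as_sweep,
    assembly_stats,
    compare_to_reference,
    coverage_binned_recovery,
    n50,
    read_hits,
)
from txconsensus.seqio import SequenceRecord

from helpers import rc


def _brute_force_n50(lengths):
    ordered = sorted(lengths, reverse=True)
    total = sum(ordered)
    for k in range(1, len(ordered) + 1):
        if sum(ordered[:k]) >= total / 2:
            return ordered[k - 1]


class TestN50:
    def test_uniform_lengths(self):
        assert n50([300, 300, 300, 300]) == 300

    def test_forced_by_definition(self):
        assert n50([1000, 500, 500]) == 1000

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            n50([])

    @given(st.lists(st.integers(1, 10000), min_size=1, max_size=1000))
    def test_matches_quadratic_oracle(self, lengths):
        assert n50(lengths) == _brute_force_n50(lengths)


def test_assembly_stats_fields(rng):
    records = [
        SequenceRecord(f"r{i}", "A" * L) for i, L in enumerate([100, 200, 300, 400])
    ]
    st_ = assembly_stats(records)
    assert st_.n_transcripts == 4
    assert (st_.smallest, st_.largest) == (100, 400)
    assert st_.median == 250
    assert st_.total_size == 1000
    assert st_.n50 == 300


class TestAnnotatability:
    def test_multiple_queries_one_subject(self):
        hits = [HitRecord(f"q{i}", "P12345", 99.0, 100, 1e-10) for i in range(3)]
        assert annotatability(hits, {"q0", "q1", "q2"}) == (3, 1)

    def test_evalue_threshold(self):
        hits = [HitRecord("q0", "P1", 99.0, 100, 1e-2)]
        assert annotatability(hits, {"q0"}) == (0, 0)
        assert annotatability([HitRecord("q0", "P1", 99.0, 100, 1e-3)], {"q0"}) == (1, 1)

    def test_unknown_query_excluded(self, caplog):
        hits = [HitRecord("ghost", "P1", 99.0, 100, 1e-9)]
        with caplog.at_level("WARNING"):
            assert annotatability(hits, {"q0"}) == (0, 0)
        assert "unknown" in caplog.text

    def test_invariant_to_row_order_and_duplication(self, rng):
        hits = [
            HitRecord(f"q{i % 5}", f"P{i % 3}", 95.0, 80, 1e-6) for i in range(20)
        ]
        base = annotatability(hits, {f"q{i}" for i in range(5)})
        doubled = hits + hits
        rng.shuffle(doubled)
        assert annotatability(doubled, {f"q{i}" for i in range(5)}) == base

    def test_planted_multiplicities(self):
        hits = [
            HitRecord("q1", "S1", 99, 50, 1e-9),
            HitRecord("q1", "S2", 99, 50, 1e-9),
            HitRecord("q2", "S1", 99, 50, 1e-9),
            HitRecord("q3", "S3", 99, 50, 1e-1),  # filtered
        ]
        assert annotatability(hits, {"q1", "q2", "q3"}) == (2, 2)


def test_read_hits_blast6(tmp_path):
    p = tmp_path / "hits.tsv"
    p.write_text("q1\ts1\t98.50\t120\t2\t0\t1\t120\t5\t124\t1e-30\t222\n")
    (hit,) = read_hits(p)
    assert hit.query_id == "q1" and hit.subject_id == "s1"
    assert hit.pct_identity == 98.5
    assert hit.aln_len == 120
    assert hit.evalue == pytest.approx(1e-30)


SENSE = sorted(
    {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"} - {"TAA", "TAG", "TGA"}
)


def _cds_seq(rng, n_aa):
    return "ATG" + "".join(rng.choice(SENSE) for _ in range(n_aa - 1))


class TestAsSweep:
    def test_single_gene_constant(self, rng):
        seq = _cds_seq(rng, 150)
        records = [SequenceRecord("g1|cds1", seq, source="CLC")]
        res = as_sweep(records, [1.0, 0.95, 0.9, 0.75])
        assert all(r.n_uniCDS == 1 for r in res.rows)
        assert res.loss_onset_aS is None

    def test_single_value_is_baseline(self, rng):
        records = [SequenceRecord("g1|cds1", _cds_seq(rng, 120), source="CLC")]
        res = as_sweep(records, [1.0])
        assert len(res.rows) == 1 and res.rows[0].aS == 1.0

    def test_loss_onset_at_planted_merge_point(self, rng):
        """A CDS sharing ~82% of its length with a longer gene merges once
        aS drops to 0.80, taking its unique annotation with it."""
        gene_a = _cds_seq(rng, 300)  # 900 nt
        # gene B: 810 nt (90% of A); first 664 nt shared with A (~82% of B),
        # divergent in-frame tail keeps the alignable fraction at ~0.82
        shared = gene_a[:664]
        tail_aa = (810 - 664) // 3
        tail = "".join(rng.choice(SENSE) for _ in range(tail_aa + 1))
        gene_b = shared + tail[: 810 - 664]
        records = [
            SequenceRecord("A|cds1", gene_a, source="CLC"),
            SequenceRecord("B|cds1", gene_b, source="CLC"),
        ]
        hits = [
            HitRecord("A|cds1", "PROT_A", 99, 300, 1e-40),
            HitRecord("B|cds1", "PROT_B", 99, 270, 1e-40),
        ]
        values = [1.00, 0.99, 0.98, 0.97, 0.96, 0.95, 0.90, 0.85, 0.80, 0.75]
        res = as_sweep(records, values, hits=hits)
        by_as = {r.aS: r for r in res.rows}
        assert by_as[0.85].n_uniCDS == 2
        assert by_as[0.80].n_uniCDS == 1
        assert res.loss_onset_aS == 0.80
        counts = [r.n_uniCDS for r in res.rows]  # rows sorted descending aS
        assert counts == sorted(counts, reverse=True)


class TestCompareToReference:
    def test_verbatim_copy_recovered(self, rng):
        seq = "".join(rng.choice("ACGT") for _ in range(300))
        report = compare_to_reference(
            [SequenceRecord("asm1", seq)], [SequenceRecord("orig1", seq)]
        )
        assert report.missing_original_ids == set()
        assert report.invented_assembled_ids == set()

    def test_40_percent_fragment_counts_missing(self, rng):
        seq = "".join(rng.choice("ACGT") for _ in range(500))
        fragment = seq[:200]  # 40% of the original at 100% identity
        report = compare_to_reference(
            [SequenceRecord("asm1", fragment)], [SequenceRecord("orig1", seq)]
        )
        assert report.missing_original_ids == {"orig1"}
        assert report.invented_assembled_ids == {"asm1"}

    def test_reverse_complement_counts_recovered(self, rng):
        seq = "".join(rng.choice("ACGT") for _ in range(400))
        report = compare_to_reference(
            [SequenceRecord("asm1", rc(seq))], [SequenceRecord("orig1", seq)]
        )
        assert report.missing_original_ids == set()

    def test_recovery_monotone_in_coverage_threshold(self, rng):
        originals = [
            SequenceRecord(f"o{i}", "".join(rng.choice("ACGT") for _ in range(400)))
            for i in range(4)
        ]
        assembled = [
            SequenceRecord(f"a{i}", o.seq[: rng.randint(150, 400)])
            for i, o in enumerate(originals)
        ]
        prev_recovered: set[str] = set()
        for cov in (0.9, 0.7, 0.5, 0.3):
            report = compare_to_reference(assembled, originals, min_cov_of_original=cov)
            recovered = report.recovered_original_ids
            assert prev_recovered <= recovered
            prev_recovered = recovered

    def test_hits_route_matches_rule(self):
        originals = [SequenceRecord("o1", "A" * 400), SequenceRecord("o2", "C" * 400)]
        assembled = [SequenceRecord("a1", "A" * 300), SequenceRecord("a2", "G" * 300)]
        hits = [
            HitRecord("a1", "o1", 99.0, 250, 1e-50),  # 250 >= 0.5*400
            HitRecord("a2", "o2", 97.0, 300, 1e-50),  # identity below 98
        ]
        report = compare_to_reference(assembled, originals, hits=hits)
        assert report.missing_original_ids == {"o2"}
        assert report.invented_assembled_ids == {"a2"}


class TestCoverageBinnedRecovery:
    def _report(self, missing, recovered):
        from txconsensus.metrics import RecoveryReport

        r = RecoveryReport(
            n_original=len(missing) + len(recovered),
            n_assembled=0,
            missing_original_ids=set(missing),
        )
        r._original_ids = set(missing) | set(recovered)
        return r

    def test_all_missing_low_coverage(self):
        report = self._report(["m1", "m2"], ["r1"])
        below, above = coverage_binned_recovery(
            report, {"m1": 2.0, "m2": 3.0, "r1": 50.0}
        )
        assert below == 1.0 and above == 1.0

    def test_empty_missing_is_not_applicable(self):
        report = self._report([], ["r1"])
        below, above = coverage_binned_recovery(report, {"r1": 4.0})
        assert below is None
        assert above == 0.0

    def test_missing_coverage_entry_named(self):
        report = self._report(["m1"], [])
        with pytest.raises(ValueError, match="m1"):
            coverage_binned_recovery(report, {})

    def test_fractions_match_direct_counting(self, rng):
        missing = [f"m{i}" for i in range(10)]
        recovered = [f"r{i}" for i in range(15)]
        coverage = {i: rng.uniform(0, 40) for i in missing + recovered}
        report = self._report(missing, recovered)
        below, above = coverage_binned_recovery(report, coverage)
        assert below == sum(1 for i in missing if coverage[i] < 10) / 10
        assert above == sum(1 for i in recovered if coverage[i] >= 10) / 15
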