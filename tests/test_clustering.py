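from __future__ import annotations

import random

import pytest

from txconsensus.clustering import (
    ClusterParams,
    dedup_exact,
    greedy_cluster,
    local_align,
    _prefilter_min_cols,
)
from txconsensus.seqio import SequenceRecord

from helpers import rc, reference_greedy, substring_filter, sw_local_align, clusterset_as_lists


def _rand(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestLocalAlign:
    def test_identical_sequences(self, rng):
        seq = _rand(rng, 100)
        s = local_align(SequenceRecord("a", seq), SequenceRecord("b", seq))
        assert (s.identity, s.cov_short, s.cov_long, s.strand) == (1.0, 1.0, 1.0, "+")
        assert s.score == 200

    def test_exact_substring(self, rng):
        long = _rand(rng, 200)
        short = long[80:120]
        s = local_align(SequenceRecord("a", long), SequenceRecord("b", short))
        assert s.identity == 1.0
        assert s.cov_short == 1.0
        assert s.cov_long == pytest.approx(0.2)

    def test_reverse_complement_detected(self, rng):
        seq = _rand(rng, 150)
        s = local_align(SequenceRecord("a", seq), SequenceRecord("b", rc(seq)))
        assert s.strand == "-"
        assert s.identity == 1.0

    def test_n_matches_nothing(self):
        s = local_align(SequenceRecord("a", "NNNNNNNNNN"), SequenceRecord("b", "NNNNNNNNNN"))
        assert s.score == 0 and s.identity == 0.0

    def test_single_nucleotide_inputs(self):
        s = local_align(SequenceRecord("a", "A"), SequenceRecord("b", "A"))
        assert s.score == 2 and s.cov_short == 1.0

    @pytest.mark.parametrize("n_subs", [1, 3, 7])
    def test_planted_substitutions_match_dp_oracle(self, rng, n_subs):
        """Substitution-only pairs have a unique optimum: full agreement."""
        a = _rand(rng, 150)
        chars = list(a)
        for p in rng.sample(range(5, 145), n_subs):
            chars[p] = rng.choice([x for x in "ACGT" if x != chars[p]])
        b = "".join(chars)
        got = local_align(SequenceRecord("a", a), SequenceRecord("b", b))
        want = sw_local_align(a, b)
        assert got.score == want.score
        assert got.identity == pytest.approx(want.identity)
        assert got.cov_short == pytest.approx(want.cov_short)
        assert got.cov_long == pytest.approx(want.cov_long)
        assert got.strand == want.strand

    def test_random_pairs_score_matches_dp_oracle(self, rng):
        """On arbitrary pairs (including gapped optima) the best score and
        strand must agree with the exhaustive DP."""
        for i in range(12):
            a = _rand(rng, rng.randint(40, 160))
            if i % 3 == 0:
                b = _rand(rng, rng.randint(40, 160))
            else:  # related with an indel and substitutions
                cut = rng.randrange(10, len(a) - 10)
                b = a[:cut] + a[cut + rng.randint(1, 4):]
                chars = list(b)
                for p in rng.sample(range(len(chars)), 2):
                    chars[p] = rng.choice([x for x in "ACGT" if x != chars[p]])
                b = "".join(chars)
            got = local_align(SequenceRecord("a", a), SequenceRecord("b", b))
            want = sw_local_align(a, b)
            assert got.score == want.score


class TestGreedyCluster:
    def test_three_identical_sequences_one_cluster(self, rng):
        seq = _rand(rng, 120)
        records = [SequenceRecord(f"s{i}", seq) for i in range(3)]
        cs = greedy_cluster(records, ClusterParams(c=1.0, aS=1.0, aL=0.005))
        assert len(cs) == 1
        assert cs.clusters[0].representative.id == "s0"

    def test_unrelated_sequences_stay_apart(self, rng):
        records = [
            SequenceRecord("a", _rand(rng, 200)),
            SequenceRecord("b", _rand(rng, 200)),
        ]
        cs = greedy_cluster(records, ClusterParams(c=0.98, aS=0.75, aL=0.005))
        assert len(cs) == 2

    def test_duplicate_ids_rejected(self):
        records = [SequenceRecord("x", "ACGTACGT"), SequenceRecord("x", "ACGTACGA")]
        with pytest.raises(ValueError, match="duplicate"):
            greedy_cluster(records, ClusterParams())

    def test_partition_property(self, rng):
        from helpers import random_instance

        records = random_instance(rng, n_max=15)
        cs = greedy_cluster(records, ClusterParams(c=0.98, aS=0.9, aL=0.005))
        assert sorted(cs.all_member_ids()) == sorted(r.id for r in records)

    def test_members_reverify_against_thresholds(self, rng):
        """Every (member, representative) pair must satisfy the run's
        thresholds when re-aligned with the exhaustive DP kernel."""
        from helpers import random_instance

        records = random_instance(rng, n_max=10)
        params = ClusterParams(c=0.98, aS=0.9, aL=0.005)
        cs = greedy_cluster(records, params)
        by_id = {r.id: r for r in records}
        for cluster in cs.clusters:
            rep = by_id[cluster.representative.id]
            for member in cluster.members:
                if member.is_representative:
                    continue
                s = sw_local_align(rep.seq, by_id[member.id].seq)
                assert s.identity >= params.c - 1e-9
                assert s.cov_short >= params.aS - 1e-9
                assert s.cov_long >= params.aL - 1e-9

    def test_order_invariance(self, rng):
        from helpers import random_instance

        records = random_instance(rng, n_max=12)
        params = ClusterParams(c=0.98, aS=0.95, aL=0.005)
        baseline = clusterset_as_lists(greedy_cluster(records, params))
        for _ in range(3):
            shuffled = records[:]
            rng.shuffle(shuffled)
            assert clusterset_as_lists(greedy_cluster(shuffled, params)) == baseline

    def test_workers_do_not_change_results(self, rng):
        from helpers import random_instance

        records = random_instance(rng, n_max=10)
        params = ClusterParams(c=0.98, aS=0.9, aL=0.005)
        one = clusterset_as_lists(greedy_cluster(records, params, workers=1))
        four = clusterset_as_lists(greedy_cluster(records, params, workers=4))
        assert one == four

    def test_prefilter_never_changes_results(self, rng):
        from helpers import random_instance

        for _ in range(5):
            records = random_instance(rng, n_max=10)
            for aS in (1.0, 0.8):
                params = ClusterParams(c=0.98, aS=aS, aL=0.005)
                with_pf = clusterset_as_lists(greedy_cluster(records, params, prefilter=True))
                without = clusterset_as_lists(greedy_cluster(records, params, prefilter=False))
                assert with_pf == without

    def test_prefilter_bound_disables_when_unsafe(self):
        assert _prefilter_min_cols(1.0, 16) == 16
        assert _prefilter_min_cols(0.98, 16) == 25
        assert _prefilter_min_cols(0.9, 16) is None  # c/(1-c)=9 < k


class TestDedupExact:
    def test_exact_substring_removed(self):
        records = [
            SequenceRecord("long", "AAACCCGGG"),
            SequenceRecord("short", "CCCGG"),
        ]
        retained, cs = dedup_exact(records)
        assert [r.id for r in retained] == ["long"]
        assert len(cs) == 1

    def test_one_mismatch_keeps_both(self):
        records = [
            SequenceRecord("a", "AAACCCGGGTTT"),
            SequenceRecord("b", "AAACCCGGGTTA"),
        ]
        retained, _ = dedup_exact(records)
        assert {r.id for r in retained} == {"a", "b"}

    def test_reverse_complement_duplicate_removed(self, rng):
        seq = _rand(rng, 80)
        records = [
            SequenceRecord("fwd", seq + _rand(rng, 40)),
            SequenceRecord("rev", rc(seq)),
        ]
        retained, cs = dedup_exact(records)
        assert [r.id for r in retained] == ["fwd"]
        assert cs.clusters[0].members[1].strand == "-"

    def test_matches_substring_filter_oracle(self, rng):
        for _ in range(5):
            base = [_rand(rng, rng.randint(60, 400)) for _ in range(6)]
            records = []
            for i in range(25):
                src = rng.choice(base)
                kind = rng.random()
                if kind < 0.3:
                    seq = src
                elif kind < 0.6:
                    n = rng.randint(20, len(src))
                    off = rng.randint(0, len(src) - n)
                    seq = src[off:off + n]
                    if rng.random() < 0.5:
                        seq = rc(seq)
                else:
                    seq = _rand(rng, rng.randint(40, 200))
                records.append(SequenceRecord(f"r{i:02d}", seq))
            retained, _ = dedup_exact(records)
            assert [r.id for r in retained] == substring_filter(records)


def test_greedy_matches_reference_implementation(rng):
    """Spot check (the acceptance suite runs this at scale): identical
    cluster assignments to an independent greedy using the full kernel."""
    from helpers import random_instance

    records = random_instance(rng, n_max=10)
    for c, aS in ((1.0, 1.0), (0.98, 0.95)):
        params = ClusterParams(c=c, aS=aS, aL=0.005)
        assert clusterset_as_lists(greedy_cluster(records, params)) == reference_greedy(
            records, c, aS, 0.005
        )
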