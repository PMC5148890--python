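"""Greedy incremental nucleotide clustering with identity/coverage semantics.

Redundancy removal between and within assemblies is expressed as greedy
clustering in the CD-HIT-EST style: sequences are visited longest-first and
each either joins the first existing cluster whose representative it matches,
or founds a new cluster.  "Matches" means a *local* alignment (the -G 0
convention) satisfying three thresholds simultaneously:

* identity ``c``    — identical columns / alignment columns (gaps count),
* ``aS``            — aligned fraction of the shorter sequence,
* ``aL``            — aligned fraction of the longer sequence.

The strict pass (c=1.00, aS=1.00, aL=0.005) removes transcripts that are
exact duplicates or exact substrings of a longer transcript, on either
strand; the relaxed pass (c=0.98) later collapses coding sequences that
differ only by sequencing error.

The pairwise kernel is an affine-gap Smith-Waterman (match +2, mismatch -3,
gap open -5, gap extend -2, N matches nothing) provided by Biopython's
PairwiseAligner.  A k-mer prefilter skips pairs that provably cannot reach
the thresholds; it never changes results.
"""

from __future__ import annotations

import math
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import SequenceRecord, reverse_complement

__all__ = [
    "ClusterParams",
    "AlignmentSummary",
    "ClusterMember",
    "Cluster",
    "ClusterSet",
    "local_align",
    "greedy_cluster",
    "dedup_exact",
]

MATCH = 2
MISMATCH = -3
GAP_OPEN = -5  # score of the first column of a gap
GAP_EXTEND = -2  # score of each further column

_EPS = 1e-9


@dataclass(frozen=True)
class ClusterParams:
    """Thresholds of one clustering pass (CD-HIT-EST -c/-aS/-aL, -G 0)."""

    c: float = 1.0
    aS: float = 1.0
    aL: float = 0.005
    both_strands: bool = True
    identity_mode: str = "local"

    def __post_init__(self) -> None:
        for name in ("c", "aS", "aL"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.identity_mode != "local":
            raise ValueError("only local identity mode is supported")


@dataclass(frozen=True)
class AlignmentSummary:
    """Quantities of the best local alignment that the thresholds act on."""

    identity: float
    cov_short: float
    cov_long: float
    strand: str
    score: int
    cov_a: float = 0.0
    cov_b: float = 0.0

    def passes(self, params: ClusterParams) -> bool:
        return (
            self.identity >= params.c - _EPS
            and self.cov_short >= params.aS - _EPS
            and self.cov_long >= params.aL - _EPS
        )


@dataclass
class ClusterMember:
    id: str
    length: int
    is_representative: bool = False
    identity: Optional[float] = None
    strand: str = "+"
    cov_short: Optional[float] = None
    cov_long: Optional[float] = None


@dataclass
class Cluster:
    members: list[ClusterMember] = field(default_factory=list)

    @property
    def representative(self) -> ClusterMember:
        for m in self.members:
            if m.is_representative:
                return m
        raise ValueError("cluster has no representative")

    @property
    def member_ids(self) -> list[str]:
        return [m.id for m in self.members]


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    params: Optional[ClusterParams] = None

    def __len__(self) -> int:
        return len(self.clusters)

    def all_member_ids(self) -> list[str]:
        return [m.id for c in self.clusters for m in c.members]

    def representative_ids(self) -> list[str]:
        return [c.representative.id for c in self.clusters]

    def cluster_of(self) -> dict[str, int]:
        """Map member id -> cluster index."""
        return {m.id: i for i, c in enumerate(self.clusters) for m in c.members}


# ---------------------------------------------------------------------------
# pairwise kernel
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array("ACGTN", dims=2)
    for x in "ACGTN":
        for y in "ACGTN":
            # N matches nothing, not even another N
            matrix[x, y] = MATCH if (x == y and x != "N") else MISMATCH
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_ALIGNER: Optional[Align.PairwiseAligner] = None


def _aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        _ALIGNER = _make_aligner()
    return _ALIGNER


def _summarize(aln, seq_a: str, seq_b_oriented: str, strand: str) -> AlignmentSummary:
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return AlignmentSummary(0.0, 0.0, 0.0, "+", 0)
    matches = 0
    columns = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        columns += a1 - a0
        matches += sum(
            1
            for x, y in zip(seq_a[a0:a1], seq_b_oriented[b0:b1])
            if x == y and x != "N"
        )
    for i in range(1, len(blocks_a)):
        columns += (blocks_a[i][0] - blocks_a[i - 1][1]) + (
            blocks_b[i][0] - blocks_b[i - 1][1]
        )
    matches = int(matches)
    columns = int(columns)
    span_a = int(blocks_a[-1][1] - blocks_a[0][0])
    span_b = int(blocks_b[-1][1] - blocks_b[0][0])
    cov_a = span_a / len(seq_a)
    cov_b = span_b / len(seq_b_oriented)
    if len(seq_a) <= len(seq_b_oriented):
        cov_short, cov_long = cov_a, cov_b
    else:
        cov_short, cov_long = cov_b, cov_a
    return AlignmentSummary(
        identity=matches / columns,
        cov_short=cov_short,
        cov_long=cov_long,
        strand=strand,
        score=int(aln.score),
        cov_a=cov_a,
        cov_b=cov_b,
    )


def _min_passing_score(params: ClusterParams, len_a: int, len_b: int) -> float:
    """Lower bound on the score of any threshold-passing alignment.

    A passing alignment spans >= max(aS*len_short, aL*len_long) columns with
    at least a fraction ``c`` of them matching (+2 each); every non-match
    column costs at most 5.  If 7c-5 <= 0 the bound is vacuous.
    """
    slope = 7.0 * params.c - 5.0
    if slope <= 0:
        return -math.inf
    min_cols = max(params.aS * min(len_a, len_b), params.aL * max(len_a, len_b))
    return slope * min_cols - _EPS


def local_align(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    both_strands: bool = True,
) -> AlignmentSummary:
    """Best-scoring local alignment summary of two sequences.

    With ``both_strands`` the better of the forward and reverse-complement
    orientation of ``b`` is reported (ties prefer "+").
    """
    seq_a = a.seq if isinstance(a, SequenceRecord) else a
    seq_b = b.seq if isinstance(b, SequenceRecord) else b
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")
    aligner = _aligner()
    best = None
    for strand, oriented in (("+", seq_b), ("-", reverse_complement(seq_b))):
        alns = aligner.align(seq_a, oriented)
        summary = (
            _summarize(alns[0], seq_a, oriented, strand)
            if alns.score > 0
            else AlignmentSummary(0.0, 0.0, 0.0, "+", 0)
        )
        if best is None or summary.score > best.score:
            best = summary
        if not both_strands:
            break
    return best


def _align_for_thresholds(
    seq_a: str, seq_b: str, params: ClusterParams
) -> Optional[AlignmentSummary]:
    """Like :func:`local_align` but may return None early when no alignment
    of the pair can possibly pass ``params`` (decided on score alone)."""
    aligner = _aligner()
    bound = _min_passing_score(params, len(seq_a), len(seq_b))
    best: Optional[AlignmentSummary] = None
    for strand, oriented in (("+", seq_b), ("-", reverse_complement(seq_b))):
        score = aligner.score(seq_a, oriented)
        if score >= bound and score > 0:
            summary = _summarize(aligner.align(seq_a, oriented)[0], seq_a, oriented, strand)
            if best is None or summary.score > best.score:
                best = summary
        if not params.both_strands:
            break
    return best


# ---------------------------------------------------------------------------
# k-mer prefilter
# ---------------------------------------------------------------------------

# 4^16 possible k-mers keeps chance collisions between unrelated ~kb-scale
# sequences negligible, while any alignment at c >= 0.94 over >= ~30 columns
# still must contain a gapless 16-mer match (see _prefilter_min_cols).
PREFILTER_K = 16


def _prefilter_min_cols(c: float, k: int = PREFILTER_K) -> Optional[int]:
    """Smallest alignment-column count above which any alignment at identity
    >= c must contain a gapless run of k matches (hence a shared k-mer).

    With e <= (1-c)*cols non-match columns, the longest match run is at least
    c*cols/((1-c)*cols + 1); the bound tends to c/(1-c), so for c too small
    relative to k no column count guarantees a run and the prefilter is
    disabled (returns None).
    """
    if c >= 1.0:
        return k
    if c / (1.0 - c) <= k:
        return None
    return max(k, math.ceil(k / (c - k * (1.0 - c))))


def _kmers(seq: str, k: int = PREFILTER_K) -> frozenset[str]:
    return frozenset(
        kmer for i in range(len(seq) - k + 1) if "N" not in (kmer := seq[i : i + k])
    )


# ---------------------------------------------------------------------------
# greedy clustering
# ---------------------------------------------------------------------------

def _canonical_order(rec: SequenceRecord) -> tuple:
    return (-len(rec.seq), rec.id)


def _batch_align(args) -> list[Optional[AlignmentSummary]]:
    member_seq, rep_seqs, params = args
    return [_align_for_thresholds(rep_seq, member_seq, params) for rep_seq in rep_seqs]


def greedy_cluster(
    records: Sequence[SequenceRecord],
    params: ClusterParams,
    *,
    order_key: Optional[Callable[[SequenceRecord], tuple]] = None,
    prefilter: bool = True,
    workers: int = 1,
) -> ClusterSet:
    """Cluster records greedily, longest first.

    Records are visited in canonical order (length descending, then id
    ascending, unless ``order_key`` overrides the tie-break); each joins the
    first cluster, in creation order, whose representative satisfies all of
    identity >= c, cov_short >= aS and cov_long >= aL, or founds a new
    cluster.  The result is independent of the input order, of ``prefilter``
    and of ``workers``.
    """
    if not records:
        raise ValueError("no records to cluster")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValueError(f"duplicate id {dup!r}")

    ordered = sorted(records, key=order_key or _canonical_order)
    exact_mode = params.c >= 1.0 and params.aS >= 1.0
    min_cols = _prefilter_min_cols(params.c) if prefilter else None

    clusters: list[Cluster] = []
    rep_seqs: list[str] = []
    rep_kmers: list[frozenset[str]] = []
    kmer_index: dict[str, list[int]] = {}
    pool = ProcessPoolExecutor(max_workers=workers) if workers > 1 else None

    try:
        for rec in ordered:
            seq = rec.seq
            kmers = _kmers(seq)
            if params.both_strands:
                kmers = kmers | _kmers(reverse_complement(seq))
            use_prefilter = (
                prefilter
                and min_cols is not None
                and math.ceil(params.aS * len(seq)) >= min_cols
            )
            if use_prefilter:
                candidates = set()
                for kmer in kmers:
                    candidates.update(kmer_index.get(kmer, ()))
            else:
                candidates = None  # all clusters are candidates

            joined = _scan_clusters(
                rec, clusters, rep_seqs, candidates, params, exact_mode, pool
            )
            if not joined:
                clusters.append(
                    Cluster(members=[ClusterMember(rec.id, len(seq), is_representative=True)])
                )
                idx = len(clusters) - 1
                rep_seqs.append(seq)
                rep_kmers.append(kmers)
                for kmer in kmers:
                    kmer_index.setdefault(kmer, []).append(idx)
    finally:
        if pool is not None:
            pool.shutdown()

    return ClusterSet(clusters=clusters, params=params)


def _exact_summary(
    member_seq: str, rep_seq: str, both_strands: bool
) -> Optional[AlignmentSummary]:
    """Substring containment check, equivalent to the DP kernel at
    c=1.0/aS=1.0: identity 1.0 over the full member length is achievable
    iff the member (or its reverse complement) is an exact, N-free
    substring of the representative."""
    if "N" in member_seq:
        return None
    orientations = [("+", member_seq)]
    if both_strands:
        orientations.append(("-", reverse_complement(member_seq)))
    for strand, oriented in orientations:
        if oriented in rep_seq:
            return AlignmentSummary(
                identity=1.0,
                cov_short=1.0,
                cov_long=len(member_seq) / len(rep_seq),
                strand=strand,
                score=MATCH * len(member_seq),
                cov_a=len(member_seq) / len(rep_seq),
                cov_b=1.0,
            )
    return None


def _scan_clusters(
    rec: SequenceRecord,
    clusters: list[Cluster],
    rep_seqs: list[str],
    candidates: Optional[set[int]],
    params: ClusterParams,
    exact_mode: bool,
    pool: Optional[ProcessPoolExecutor],
) -> bool:
    """Try to place ``rec`` in the first matching cluster; True if joined."""
    idxs = [
        i for i in range(len(clusters)) if candidates is None or i in candidates
    ]

    def register(i: int, summary: AlignmentSummary) -> None:
        clusters[i].members.append(
            ClusterMember(
                id=rec.id,
                length=len(rec.seq),
                identity=summary.identity,
                strand=summary.strand if params.both_strands else "+",
                cov_short=summary.cov_short,
                cov_long=summary.cov_long,
            )
        )

    if exact_mode:
        for i in idxs:
            summary = _exact_summary(rec.seq, rep_seqs[i], params.both_strands)
            if summary is not None and summary.passes(params):
                register(i, summary)
                return True
        return False

    if pool is not None and len(idxs) > 1:
        chunks = [(rep_seqs[i], [rec.seq], params) for i in idxs]
        results = list(pool.map(_batch_align, chunks))
        for i, res in zip(idxs, results):
            summary = res[0]
            if summary is not None and summary.passes(params):
                register(i, summary)
                return True
        return False

    for i in idxs:
        summary = _align_for_thresholds(rep_seqs[i], rec.seq, params)
        if summary is not None and summary.passes(params):
            register(i, summary)
            return True
    return False


def dedup_exact(
    records: Sequence[SequenceRecord],
) -> tuple[list[SequenceRecord], ClusterSet]:
    """Remove strictly redundant transcripts within one assembly.

    A transcript is removed iff it (or its reverse complement) aligns to a
    retained longer transcript at 100% identity over 100% of its own length,
    i.e. it is an exact substring.  Retained transcripts are the cluster
    representatives, returned longest first.
    """
    params = ClusterParams(c=1.0, aS=1.0, aL=0.005, both_strands=True)
    cluster_set = greedy_cluster(records, params)
    by_id = {r.id: r for r in records}
    retained = [by_id[c.representative.id] for c in cluster_set.clusters]
    return retained, cluster_set
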