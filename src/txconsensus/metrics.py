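"""Assembly statistics, annotatability metrics and reference recovery.

Length statistics (N50 etc.) are cheap but weak evidence of assembly
quality; the more informative metrics here are annotation-based (how many
CDSs find a similarity-search hit, and how many *distinct* database entries
are hit) and, when a ground-truth transcript set exists, the two-way
recovery comparison: originals with no qualifying alignment in the assembly
("missing") and assembled transcripts with no qualifying alignment to any
original ("invented", i.e. bioinformatic artifacts).
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .clustering import (
    ClusterParams,
    PREFILTER_K,
    _kmers,
    _prefilter_min_cols,
    greedy_cluster,
    local_align,
)
from .seqio import SequenceRecord, reverse_complement

__all__ = [
    "AssemblyStats",
    "HitRecord",
    "RecoveryReport",
    "SweepRow",
    "SweepResult",
    "n50",
    "assembly_stats",
    "read_hits",
    "annotatability",
    "as_sweep",
    "compare_to_reference",
    "coverage_binned_recovery",
    "read_coverage_table",
]

logger = logging.getLogger(__name__)

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

DEFAULT_MAX_EVALUE = 1e-3


@dataclass(frozen=True)
class AssemblyStats:
    n_transcripts: int
    smallest: int
    largest: int
    median: float
    total_size: int
    n50: int


@dataclass(frozen=True)
class HitRecord:
    """One row of a 12-column tabular similarity-search result."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    evalue: float


@dataclass
class RecoveryReport:
    """Two-way comparison of an assembly against reference transcripts.

    An original is recovered iff some assembled transcript aligns to it at
    >= ``min_identity`` over >= ``min_cov_of_original`` of the ORIGINAL's
    length; an assembled transcript is invented iff it qualifies against no
    original under the same rule.
    """

    n_original: int
    n_assembled: int
    missing_original_ids: set[str] = field(default_factory=set)
    invented_assembled_ids: set[str] = field(default_factory=set)
    min_identity: float = 0.98
    min_cov_of_original: float = 0.5

    @property
    def recovered_original_ids(self) -> set[str]:
        return self._original_ids - self.missing_original_ids

    _original_ids: set[str] = field(default_factory=set)


def n50(lengths: Sequence[int]) -> int:
    """Length at which the descending cumulative sum first reaches half the total."""
    if not lengths:
        raise ValueError("empty length list")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2.0
    acc = 0
    for L in ordered:
        acc += L
        if acc >= half:
            return L
    raise AssertionError("unreachable")


def assembly_stats(records: Sequence[SequenceRecord]) -> AssemblyStats:
    if not records:
        raise ValueError("no records")
    lengths = [len(r.seq) for r in records]
    return AssemblyStats(
        n_transcripts=len(lengths),
        smallest=min(lengths),
        largest=max(lengths),
        median=statistics.median(lengths),
        total_size=sum(lengths),
        n50=n50(lengths),
    )


# ---------------------------------------------------------------------------
# annotatability
# ---------------------------------------------------------------------------

def read_hits(path: str | Path) -> list[HitRecord]:
    """Parse a 12-column tabular hit file (BLAST outfmt-6 dialect)."""
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS, comment="#")
    return [
        HitRecord(
            query_id=str(row.qseqid),
            subject_id=str(row.sseqid),
            pct_identity=float(row.pident),
            aln_len=int(row.length),
            evalue=float(row.evalue),
        )
        for row in df.itertuples(index=False)
    ]


def annotatability(
    hits: Iterable[HitRecord],
    query_ids: set[str],
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> tuple[int, int]:
    """(number of queries with >= 1 qualifying hit, number of distinct
    subjects hit).  Hits above the e-value threshold are ignored; hits whose
    query is not in ``query_ids`` are excluded with a warning."""
    queries_with_hit: set[str] = set()
    subjects: set[str] = set()
    unknown: set[str] = set()
    for hit in hits:
        if hit.evalue > max_evalue:
            continue
        if hit.query_id not in query_ids:
            unknown.add(hit.query_id)
            continue
        queries_with_hit.add(hit.query_id)
        subjects.add(hit.subject_id)
    if unknown:
        logger.warning(
            "%d hit(s) referencing unknown queries excluded (e.g. %s)",
            len(unknown), sorted(unknown)[0],
        )
    return len(queries_with_hit), len(subjects)


# ---------------------------------------------------------------------------
# aS sweep
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepRow:
    aS: float
    n_uniCDS: int
    n_queries_with_hit: Optional[int] = None
    n_unique_subjects: Optional[int] = None


@dataclass
class SweepResult:
    rows: list[SweepRow]
    loss_onset_aS: Optional[float] = None  # largest aS losing unique subjects

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])


def as_sweep(
    cds_records: Sequence[SequenceRecord],
    aS_values: Sequence[float],
    base_params: Optional[ClusterParams] = None,
    hits: Optional[Sequence[HitRecord]] = None,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    order_key=None,
) -> SweepResult:
    """Re-cluster the CDS set at each aS value and measure the outcome.

    The annotatability of each clustering is measured on the representative
    (uniCDS) ids.  The "information loss onset" is the largest aS value at
    which the number of unique subjects drops below the aS=1.00 baseline;
    the baseline is computed even when 1.00 is not in ``aS_values``.
    """
    base = base_params or ClusterParams(c=0.98, aS=1.0, aL=0.005, both_strands=False)
    values = sorted(set(aS_values), reverse=True)
    if any(not 0 < v <= 1 for v in values):
        raise ValueError("aS values must be in (0, 1]")

    def run(aS: float) -> SweepRow:
        params = ClusterParams(c=base.c, aS=aS, aL=base.aL, both_strands=base.both_strands)
        cs = greedy_cluster(cds_records, params, order_key=order_key)
        reps = set(cs.representative_ids())
        if hits is not None:
            n_hit, n_subj = annotatability(hits, reps, max_evalue)
        else:
            n_hit = n_subj = None
        return SweepRow(aS=aS, n_uniCDS=len(cs), n_queries_with_hit=n_hit,
                        n_unique_subjects=n_subj)

    rows = [run(v) for v in values]
    loss_onset = None
    if hits is not None:
        baseline = next((r for r in rows if r.aS == 1.0), None) or run(1.0)
        for row in rows:  # descending aS; first drop is the largest aS
            if row.aS < 1.0 and row.n_unique_subjects < baseline.n_unique_subjects:
                loss_onset = row.aS
                break
    return SweepResult(rows=rows, loss_onset_aS=loss_onset)


# ---------------------------------------------------------------------------
# reference recovery
# ---------------------------------------------------------------------------

def compare_to_reference(
    assembled: Sequence[SequenceRecord],
    originals: Sequence[SequenceRecord],
    min_identity: float = 0.98,
    min_cov_of_original: float = 0.5,
    hits: Optional[Sequence[HitRecord]] = None,
) -> RecoveryReport:
    """Two-way recovery comparison between an assembly and reference
    transcripts.

    With ``hits`` (query = assembled id, subject = original id) the rule is
    applied to the tabulated best alignments; otherwise every pair is aligned
    with the built-in local-alignment kernel (suitable for desk-scale sets
    only).  Coverage is always measured on the original transcript and only
    the single best alignment is considered (no chaining of fragments).
    """
    if not assembled or not originals:
        raise ValueError("both sequence sets must be non-empty")
    original_len = {r.id: len(r.seq) for r in originals}
    assembled_ids = {r.id for r in assembled}
    recovered: set[str] = set()
    qualifying_assembled: set[str] = set()

    if hits is not None:
        for hit in hits:
            if hit.query_id not in assembled_ids or hit.subject_id not in original_len:
                continue
            if (
                hit.pct_identity >= min_identity * 100.0
                and hit.aln_len >= min_cov_of_original * original_len[hit.subject_id]
            ):
                recovered.add(hit.subject_id)
                qualifying_assembled.add(hit.query_id)
    else:
        # A qualifying alignment (identity >= min_identity over >=
        # min_cov_of_original of the original) must contain a long gapless
        # exact run, hence a shared k-mer; pairs sharing none are skipped.
        min_cols_guard = _prefilter_min_cols(min_identity)
        assembled_kmers = {
            a.id: _kmers(a.seq) | _kmers(reverse_complement(a.seq)) for a in assembled
        }
        for o in originals:
            o_kmers = _kmers(o.seq)
            min_cols = min_cov_of_original * len(o.seq)
            use_prefilter = (
                min_cols_guard is not None
                and min_cols >= min_cols_guard
                and len(o.seq) >= PREFILTER_K
            )
            for a in assembled:
                if use_prefilter and not (o_kmers & assembled_kmers[a.id]):
                    continue
                summary = local_align(o, a, both_strands=True)
                cov_original = summary.cov_a  # o was passed first
                if (
                    summary.identity >= min_identity
                    and cov_original >= min_cov_of_original
                ):
                    recovered.add(o.id)
                    qualifying_assembled.add(a.id)

    report = RecoveryReport(
        n_original=len(originals),
        n_assembled=len(assembled),
        missing_original_ids=set(original_len) - recovered,
        invented_assembled_ids=assembled_ids - qualifying_assembled,
        min_identity=min_identity,
        min_cov_of_original=min_cov_of_original,
    )
    report._original_ids = set(original_len)
    return report


def read_coverage_table(path: str | Path) -> dict[str, float]:
    """Two-column TSV (id, fold-coverage) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "coverage"], comment="#")
    return dict(zip(df["id"].astype(str), df["coverage"].astype(float)))


def coverage_binned_recovery(
    report: RecoveryReport,
    coverage: Mapping[str, float],
    threshold: float = 10.0,
) -> tuple[Optional[float], Optional[float]]:
    """Fractions tying recovery failures to read coverage.

    Returns (fraction of missing originals with coverage < threshold,
    fraction of recovered originals with coverage >= threshold); a fraction
    is None when its denominator is empty.
    """
    for ids in (report.missing_original_ids, report.recovered_original_ids):
        for i in ids:
            if i not in coverage:
                raise ValueError(f"no coverage entry for original {i!r}")
    missing = report.missing_original_ids
    recovered = report.recovered_original_ids
    frac_missing_below = (
        sum(1 for i in missing if coverage[i] < threshold) / len(missing)
        if missing else None
    )
    frac_recovered_above = (
        sum(1 for i in recovered if coverage[i] >= threshold) / len(recovered)
        if recovered else None
    )
    return frac_missing_below, frac_recovered_above
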