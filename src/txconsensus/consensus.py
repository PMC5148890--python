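"""Consensus pipeline: merge assemblies, reduce to unique CDSs, classify.

The pipeline takes two or more labelled de novo assemblies of the same
RNA-seq dataset and produces a non-redundant coding transcriptome:

1. harmonize record names so provenance is traceable,
2. remove strictly redundant transcripts within each assembly
   (c=1.00 / aS=1.00 / aL=0.005, both strands),
3. concatenate the survivors,
4. extract CDSs (ORFs >= 100 aa, UTRs removed),
5. cluster the CDSs at 98% local identity (aS configurable, 1.00..0.75),
6. keep per cluster the transcript that generated the longest CDS ("uniCDS"),
7. classify every cluster by which assemblers contributed members,
8. measure, per assembler, how much coding sequence the consensus adds
   beyond that assembler's own longest CDS ("CDS extension"),
9. emit the final transcripts (owners of a representative CDS, UTRs intact).

Clusters contributed by a single assembler are candidate bioinformatic
artifacts; clusters present in all assemblies are the most trustworthy.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from . import seqio
from .clustering import ClusterParams, ClusterSet, greedy_cluster, dedup_exact
from .orf import CdsRecord, cds_counts, extract_cds, write_cds_fasta
from .seqio import DEFAULT_SEPARATOR, SequenceRecord

__all__ = [
    "ConsensusParams",
    "ExtensionStats",
    "ConsensusStats",
    "ConsensusResult",
    "build_category_map",
    "assign_categories",
    "compute_extensions",
    "finalize_transcripts",
    "run_consensus",
    "write_outputs",
]

logger = logging.getLogger(__name__)

CANONICAL_LABELS = ("CLC", "IDBA_tran", "Trinity")

# The paper-era aS sweep grid for the CDS clustering step.
AS_SWEEP_VALUES = (1.00, 0.99, 0.98, 0.97, 0.96, 0.95, 0.90, 0.85, 0.80, 0.75)


@dataclass(frozen=True)
class ConsensusParams:
    """Parameters of the CDS clustering step and pipeline-wide knobs.

    Defaults reproduce the published procedure: identity 0.98 (conservative
    w.r.t. the ~1% Illumina error rate), aS 1.00 (most conservative sweep
    value), aL 0.005 (admits length ratios up to 200x), ORFs >= 100 aa.
    """

    cds_identity: float = 0.98
    cds_aS: float = 1.00
    cds_aL: float = 0.005
    min_aa: int = 100
    assembler_labels: Optional[tuple[str, ...]] = None
    separator: str = DEFAULT_SEPARATOR
    cds_both_strands: bool = False  # CDSs are already strand-oriented
    category_map: Optional[dict[frozenset, int]] = None

    def cluster_params(self) -> ClusterParams:
        return ClusterParams(
            c=self.cds_identity,
            aS=self.cds_aS,
            aL=self.cds_aL,
            both_strands=self.cds_both_strands,
        )


@dataclass
class ExtensionStats:
    """Per-assembler CDS extension bookkeeping.

    A cluster counts as "extended" for an assembler when that assembler
    contributed at least one member CDS and its longest contribution is
    strictly shorter than the cluster representative; the extension is the
    length difference in bp.
    """

    n_present: int = 0
    n_extended: int = 0
    cumulated_extension_bp: int = 0

    @property
    def mean_extension_bp(self) -> float:
        return self.cumulated_extension_bp / self.n_extended if self.n_extended else 0.0


@dataclass
class ConsensusStats:
    n_concatenated_transcripts: int = 0
    n_cds: int = 0
    n_uniCDS: int = 0
    n_final_transcripts: int = 0
    n_total_cds_on_final_transcripts: int = 0
    n_multi_cds_transcripts: int = 0
    n_redundant_cds: int = 0
    intra_assembly: dict = field(default_factory=dict)  # label -> {n_in, n_retained}
    extensions: dict = field(default_factory=dict)  # label -> ExtensionStats
    category_counts: dict = field(default_factory=dict)  # category -> n clusters

    def to_dict(self) -> dict:
        d = {
            "n_concatenated_transcripts": self.n_concatenated_transcripts,
            "n_cds": self.n_cds,
            "n_uniCDS": self.n_uniCDS,
            "n_final_transcripts": self.n_final_transcripts,
            "n_total_cds_on_final_transcripts": self.n_total_cds_on_final_transcripts,
            "n_multi_cds_transcripts": self.n_multi_cds_transcripts,
            "n_redundant_cds": self.n_redundant_cds,
            "intra_assembly": self.intra_assembly,
            "category_counts": {str(k): v for k, v in sorted(self.category_counts.items())},
            "extensions": {
                label: {
                    "n_present": ext.n_present,
                    "n_extended": ext.n_extended,
                    "cumulated_extension_bp": ext.cumulated_extension_bp,
                    "mean_extension_bp": round(ext.mean_extension_bp, 2),
                }
                for label, ext in self.extensions.items()
            },
        }
        return d


@dataclass
class ConsensusResult:
    uniCDS: list[CdsRecord]
    final_transcripts: list[SequenceRecord]
    categories: list[int]  # per step-8 cluster index
    step5_clusters: dict[str, ClusterSet]
    step8_clusters: ClusterSet
    cds_records: list[CdsRecord]
    stats: ConsensusStats
    params: ConsensusParams
    labels: tuple[str, ...]

    def trace(self, unicds_id: str) -> tuple[str, str]:
        """Resolve a uniCDS id back to (assembler label, original transcript name)."""
        cds = next(c for c in self.uniCDS if c.cds_id == unicds_id)
        label, original = seqio.split_harmonized_id(
            cds.transcript_id, self.params.separator
        )
        return label, original


# ---------------------------------------------------------------------------
# categories
# ---------------------------------------------------------------------------

def build_category_map(labels: Sequence[str]) -> dict[frozenset, int]:
    """Default mapping of assembler-presence subsets to category numbers.

    For three assemblers [A, B, C] the convention is:
    1={A,B,C}, 2={A,B}, 3={A,C}, 4={B,C}, 5={A}, 6={C}, 7={B} — i.e. with
    the canonical labels, 5 = CLC-only, 6 = Trinity-only, 7 = IDBA-only.
    (Published accounts of this 7-way scheme disagree internally on the
    single-assembler ordering; this is the convention used for reported
    category counts, and it is configurable.)  For other assembler counts,
    the 2^N - 1 non-empty subsets are numbered by decreasing subset size,
    then lexicographically by label positions.
    """
    labels = list(labels)
    n = len(labels)
    subsets = []
    for mask in range(1, 2**n):
        idxs = tuple(i for i in range(n) if mask & (1 << i))
        subsets.append(idxs)
    subsets.sort(key=lambda idxs: (-len(idxs), idxs))
    if n == 3:
        # singles in label order would be A, B, C; the convention is A, C, B
        subsets = subsets[:4] + [subsets[4], subsets[6], subsets[5]]
    return {
        frozenset(labels[i] for i in idxs): cat
        for cat, idxs in enumerate(subsets, start=1)
    }


def assign_categories(
    member_labels: frozenset | set,
    labels: Sequence[str],
    category_map: Optional[dict[frozenset, int]] = None,
) -> int:
    """Category of one cluster given the set of assemblers that contributed."""
    member_labels = frozenset(member_labels)
    if not member_labels:
        raise ValueError("empty label set")
    unknown = member_labels - set(labels)
    if unknown:
        raise ValueError(f"unknown assembler label(s): {sorted(unknown)}")
    cmap = category_map or build_category_map(labels)
    return cmap[member_labels]


# ---------------------------------------------------------------------------
# extensions
# ---------------------------------------------------------------------------

def compute_extensions(
    step8_clusters: ClusterSet,
    cds_by_id: Mapping[str, CdsRecord],
    labels: Sequence[str],
) -> dict[str, ExtensionStats]:
    """Per-assembler counts of clusters where the consensus extends that
    assembler's own longest CDS, and by how many bp in total."""
    stats = {label: ExtensionStats() for label in labels}
    for cluster in step8_clusters.clusters:
        rep_len = len(cds_by_id[cluster.representative.id].nt_seq)
        longest: dict[str, int] = {}
        for member in cluster.members:
            cds = cds_by_id[member.id]
            longest[cds.source] = max(longest.get(cds.source, 0), len(cds.nt_seq))
        for label, best in longest.items():
            stats[label].n_present += 1
            if best < rep_len:
                stats[label].n_extended += 1
                stats[label].cumulated_extension_bp += rep_len - best
    return stats


# ---------------------------------------------------------------------------
# final transcript selection
# ---------------------------------------------------------------------------

def finalize_transcripts(
    representatives: Sequence[CdsRecord],
    all_cds: Sequence[CdsRecord],
    transcripts: Sequence[SequenceRecord],
) -> tuple[list[SequenceRecord], int, int]:
    """Final transcripts and redundancy bookkeeping.

    Final transcripts are the owners of at least one representative CDS
    (UTRs intact).  Returns (final transcripts, number of final transcripts
    carrying more than one CDS, number of CDSs on final transcripts that are
    cluster members but not representatives).
    """
    by_id = {t.id: t for t in transcripts}
    rep_ids = {c.cds_id for c in representatives}
    owners = {c.transcript_id for c in representatives}
    missing = owners - set(by_id)
    if missing:
        raise ValueError(
            f"representative CDS with no owning transcript: {sorted(missing)[:3]}"
        )
    final = [t for t in transcripts if t.id in owners]
    counts = cds_counts(c for c in all_cds if c.transcript_id in owners)
    n_multi = sum(1 for v in counts.values() if v > 1)
    n_redundant = sum(
        1
        for c in all_cds
        if c.transcript_id in owners and c.cds_id not in rep_ids
    )
    return final, n_multi, n_redundant


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_consensus(
    assemblies: Mapping[str, Sequence[SequenceRecord]],
    params: ConsensusParams = ConsensusParams(),
    *,
    already_harmonized: bool = False,
) -> ConsensusResult:
    """Run the whole merge/reduce/classify pipeline on labelled assemblies."""
    if not assemblies:
        raise ValueError("no assemblies given")
    labels = tuple(params.assembler_labels or assemblies.keys())
    if set(labels) != set(assemblies.keys()):
        raise ValueError("assembler_labels do not match the assemblies mapping")
    if len(labels) < 2:
        logger.warning(
            "only %d assembly given; consensus categories are degenerate", len(labels)
        )
    label_rank = {label: i for i, label in enumerate(labels)}
    stats = ConsensusStats()

    # steps 4-5: harmonize names, remove intra-assembly redundancy
    step5_clusters: dict[str, ClusterSet] = {}
    concatenated: list[SequenceRecord] = []
    for label in labels:
        records = list(assemblies[label])
        if not records:
            raise ValueError(f"assembly {label!r} is empty")
        if not already_harmonized:
            records, _ = seqio.harmonize_names(records, label, params.separator)
        retained, cs = dedup_exact(records)
        step5_clusters[label] = cs
        stats.intra_assembly[label] = {
            "n_in": len(records),
            "n_retained": len(retained),
            "redundancy_rate": 1.0 - len(retained) / len(records),
        }
        logger.info(
            "step 5 [%s]: %d -> %d transcripts", label, len(records), len(retained)
        )
        concatenated.extend(retained)

    # step 6: concatenation
    stats.n_concatenated_transcripts = len(concatenated)
    logger.info("step 6: concatenated %d transcripts", len(concatenated))

    # step 7: CDS extraction
    cds_records = extract_cds(concatenated, min_aa=params.min_aa, separator=params.separator)
    stats.n_cds = len(cds_records)
    logger.info("step 7: %d CDSs (>= %d aa)", len(cds_records), params.min_aa)
    if not cds_records:
        raise ValueError("no CDS detected in any assembly; nothing to cluster")
    cds_by_id = {c.cds_id: c for c in cds_records}

    # step 8: CDS clustering; representative = longest CDS, ties broken by
    # assembler-label order then id
    cds_seq_records = [
        SequenceRecord(id=c.cds_id, seq=c.nt_seq, source=c.source) for c in cds_records
    ]
    step8 = greedy_cluster(
        cds_seq_records,
        params.cluster_params(),
        order_key=lambda r: (-len(r.seq), label_rank[r.source], r.id),
    )
    unicds = [cds_by_id[c.representative.id] for c in step8.clusters]
    stats.n_uniCDS = len(unicds)
    logger.info("step 8: %d clusters (uniCDSs)", len(unicds))

    # classification
    cmap = params.category_map or build_category_map(labels)
    categories = []
    for cluster in step8.clusters:
        present = frozenset(cds_by_id[m.id].source for m in cluster.members)
        categories.append(assign_categories(present, labels, cmap))
    for cat in categories:
        stats.category_counts[cat] = stats.category_counts.get(cat, 0) + 1

    # extensions
    stats.extensions = compute_extensions(step8, cds_by_id, labels)

    # step 9: final transcripts
    final, n_multi, n_redundant = finalize_transcripts(unicds, cds_records, concatenated)
    stats.n_final_transcripts = len(final)
    stats.n_multi_cds_transcripts = n_multi
    stats.n_redundant_cds = n_redundant
    final_ids = {t.id for t in final}
    stats.n_total_cds_on_final_transcripts = sum(
        1 for c in cds_records if c.transcript_id in final_ids
    )
    logger.info(
        "step 9: %d final transcripts, %d multi-CDS, %d redundant CDSs",
        len(final), n_multi, n_redundant,
    )

    return ConsensusResult(
        uniCDS=unicds,
        final_transcripts=final,
        categories=categories,
        step5_clusters=step5_clusters,
        step8_clusters=step8,
        cds_records=cds_records,
        stats=stats,
        params=params,
        labels=labels,
    )


def write_outputs(result: ConsensusResult, outdir: str | Path) -> None:
    """Write the pipeline outputs: FASTAs, .clstr files, tables, stats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seqio.write_fasta(result.final_transcripts, outdir / "final_transcripts.fasta")
    write_cds_fasta(result.uniCDS, outdir / "unicds.fasta")
    for label, cs in result.step5_clusters.items():
        seqio.write_clstr(cs, outdir / f"step5_{label}.clstr")
    seqio.write_clstr(result.step8_clusters, outdir / "step8.clstr")
    cds_by_id = {c.cds_id: c for c in result.cds_records}
    with open(outdir / "categories.tsv", "w") as fh:
        fh.write("cluster_id\tcategory\tmember_labels\trepresentative_cds\n")
        for i, (cluster, cat) in enumerate(
            zip(result.step8_clusters.clusters, result.categories)
        ):
            present = sorted({cds_by_id[m.id].source for m in cluster.members})
            fh.write(f"{i}\t{cat}\t{','.join(present)}\t{cluster.representative.id}\n")
    stats = result.stats.to_dict()
    with open(outdir / "stats.json", "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "stats.tsv", "w") as fh:
        for key in (
            "n_concatenated_transcripts", "n_cds", "n_uniCDS", "n_final_transcripts",
            "n_total_cds_on_final_transcripts", "n_multi_cds_transcripts",
            "n_redundant_cds",
        ):
            fh.write(f"{key}\t{stats[key]}\n")
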