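"""FASTA and cluster-file I/O with assembler-provenance bookkeeping.

Merging several de novo assemblies only works if every transcript in the
merged pool can be traced back to the assembler that produced it.  This
module reads assembler FASTA output into :class:`SequenceRecord` objects,
rewrites record names with a provenance prefix (``harmonize_names``), and
serializes/parses clustering results in a CD-HIT-EST-compatible ``.clstr``
dialect so downstream provenance mining works on plain text files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "DEFAULT_SEPARATOR",
    "read_fasta",
    "write_fasta",
    "harmonize_names",
    "split_harmonized_id",
    "write_clstr",
    "parse_clstr",
]

DEFAULT_SEPARATOR = "|"

# IUPAC nucleotide one-letter codes; ambiguity codes other than N collapse to N.
_AMBIGUITY = set("RYSWKMBDHV")
_VALID = set("ACGTN")
_AMBIG_TABLE = str.maketrans({c: "N" for c in _AMBIGUITY} | {"U": "T"})


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence with an assembly-provenance label."""

    id: str
    seq: str
    source: str = ""

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> str:
        return reverse_complement(self.seq)


_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def _clean_seq(raw: str, rec_id: str) -> str:
    seq = str(raw).upper().translate(_AMBIG_TABLE)
    bad = set(seq) - _VALID
    if bad:
        pos = next(i for i, c in enumerate(seq) if c in bad)
        raise ValueError(
            f"record {rec_id!r}: non-nucleotide residue {seq[pos]!r} at position {pos}"
        )
    if not seq:
        raise ValueError(f"record {rec_id!r}: empty sequence")
    return seq


def read_fasta(path: str | Path, source: str = "") -> list[SequenceRecord]:
    """Read a FASTA file into records, in file order.

    Ids are the header token up to the first whitespace.  Sequences are
    uppercased and ambiguity codes other than N are mapped to N.  Duplicate
    ids and non-nucleotide residues raise ``ValueError``.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, seq=_clean_seq(rec.seq, rec.id), source=source))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    """Write records as FASTA, ids verbatim, wrapped at `width` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def harmonize_names(
    records: Sequence[SequenceRecord],
    label: str,
    separator: str = DEFAULT_SEPARATOR,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Prefix every record id with its assembly label.

    Returns the renamed records and the old→new id mapping.  The renaming is
    injective and invertible by splitting on the separator: assembler output
    names are only required to be unique *within* one assembly, so tracing a
    merged record back to ``(assembler, original name)`` relies entirely on
    this prefix.
    """
    if not label or any(ch.isspace() for ch in label) or separator in label:
        raise ValueError(f"invalid assembly label {label!r}")
    mapping: dict[str, str] = {}
    out: list[SequenceRecord] = []
    for rec in records:
        new_id = f"{label}{separator}{rec.id}"
        if new_id in mapping.values():  # pragma: no cover - ids unique per file
            raise ValueError(f"name collision after renaming: {new_id!r}")
        mapping[rec.id] = new_id
        out.append(replace(rec, id=new_id, source=label))
    if len(set(mapping.values())) != len(mapping):
        raise ValueError("name collision after renaming")
    return out, mapping


def split_harmonized_id(rec_id: str, separator: str = DEFAULT_SEPARATOR) -> tuple[str, str]:
    """Invert :func:`harmonize_names` for one id."""
    label, sep, original = rec_id.partition(separator)
    if not sep:
        raise ValueError(f"id {rec_id!r} carries no provenance prefix")
    return label, original


# ---------------------------------------------------------------------------
# CD-HIT-compatible .clstr serialization
# ---------------------------------------------------------------------------

_CLSTR_HEADER = re.compile(r"^>Cluster\s+(\d+)\s*$")
_CLSTR_MEMBER = re.compile(
    r"^(\d+)\t(\d+)nt, >(.*)\.\.\. (?:\*|at ([+-])/(\d+(?:\.\d+)?)%)\s*$"
)


def write_clstr(clusters, path: str | Path) -> None:
    """Write a ClusterSet in the CD-HIT-EST ``.clstr`` dialect.

    Representative lines end in ``*``; member lines carry strand and percent
    identity to the representative, e.g. ``at +/98.00%``.
    """
    with open(path, "w") as fh:
        for c_idx, cluster in enumerate(clusters.clusters):
            fh.write(f">Cluster {c_idx}\n")
            for m_idx, member in enumerate(cluster.members):
                if member.is_representative:
                    fh.write(f"{m_idx}\t{member.length}nt, >{member.id}... *\n")
                else:
                    fh.write(
                        f"{m_idx}\t{member.length}nt, >{member.id}... "
                        f"at {member.strand}/{member.identity * 100:.2f}%\n"
                    )


def parse_clstr(path: str | Path):
    """Parse a ``.clstr`` file back into a ClusterSet.

    Round trip with :func:`write_clstr` preserves ids, lengths,
    representative flags, strands and identities to two decimal places.
    """
    from .clustering import Cluster, ClusterMember, ClusterSet

    clusters: list[Cluster] = []
    members: list[ClusterMember] = []
    started = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            m = _CLSTR_HEADER.match(line)
            if m:
                if started and members:
                    clusters.append(Cluster(members=members))
                    members = []
                started = True
                continue
            m = _CLSTR_MEMBER.match(line)
            if m is None or not started:
                raise ValueError(f"{path}: malformed .clstr line {lineno}: {line.rstrip()!r}")
            _, length, rec_id, strand, pct = m.groups()
            if strand is None:
                members.append(
                    ClusterMember(id=rec_id, length=int(length), is_representative=True)
                )
            else:
                members.append(
                    ClusterMember(
                        id=rec_id,
                        length=int(length),
                        is_representative=False,
                        identity=float(pct) / 100.0,
                        strand=strand,
                    )
                )
    if started and members:
        clusters.append(Cluster(members=members))
    if not clusters:
        raise ValueError(f"{path}: no clusters found")
    return ClusterSet(clusters=clusters, params=None)
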