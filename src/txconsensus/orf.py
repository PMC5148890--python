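"""Six-frame ORF detection and CDS extraction.

Transcripts assembled de novo carry UTRs and often junk sequence; only the
coding part is merged across assemblers.  An ORF here is a maximal stop-free
stretch in one of the six reading frames, reported when it encodes at least
``min_aa`` amino acids (default 100).  Within a stretch the reported CDS
starts at the first ATG when one exists; a stretch that reaches the 5'
boundary of its frame without an upstream stop codon is reported from its
start even without an ATG (5'-partial).  The stop codon is excluded from the
CDS sequence and coordinates.  Codons containing N translate to X and never
count as stop codons.  Detection is purely structural (length + frame);
no coding-likelihood model is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .seqio import DEFAULT_SEPARATOR, SequenceRecord, reverse_complement

__all__ = [
    "CdsRecord",
    "find_orfs",
    "extract_cds",
    "cds_counts",
    "write_cds_fasta",
    "write_peptide_fasta",
    "translate",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate(nt_seq: str) -> str:
    """Translate an in-frame nucleotide sequence (table 1; N-codons -> X)."""
    aa = []
    for i in range(0, len(nt_seq) - len(nt_seq) % 3, 3):
        codon = nt_seq[i : i + 3]
        aa.append("X" if "N" in codon else _CODON_TABLE[codon])
    return "".join(aa)


@dataclass(frozen=True)
class CdsRecord:
    """One ORF-derived coding sequence.

    ``start``/``end`` are 0-based half-open coordinates on the *forward*
    strand of the transcript; ``nt_seq`` is strand-adjusted (5'->3' of the
    coding strand) and excludes the stop codon; ``frame`` is the offset of
    the reading frame on the coding strand.
    """

    cds_id: str
    transcript_id: str
    source: str
    strand: str
    frame: int
    start: int
    end: int
    aa_len: int
    nt_seq: str
    completeness: str

    def __post_init__(self) -> None:
        if self.end - self.start != 3 * self.aa_len:
            raise ValueError("CDS coordinates inconsistent with aa length")


def _stretch_orfs(seq: str, frame: int, min_aa: int):
    """Yield (start, end, completeness) of qualifying ORFs in one frame of
    one strand, coordinates on `seq` (the coding strand)."""
    n = len(seq)
    stretch_start = frame
    has_upstream_stop = False
    pos = frame
    while pos + 3 <= n + 3:  # one extra iteration flushes the final stretch
        at_end = pos + 3 > n
        codon = None if at_end else seq[pos : pos + 3]
        is_stop = codon in STOP_CODONS if codon is not None else False
        if at_end or is_stop:
            stretch_end = pos  # codon-aligned, excludes the stop
            if stretch_end > stretch_start:
                atg = None
                for p in range(stretch_start, stretch_end, 3):
                    if seq[p : p + 3] == START_CODON:
                        atg = p
                        break
                if atg is not None:
                    start = atg
                    completeness = "complete" if is_stop else "3prime_partial"
                elif not has_upstream_stop:
                    start = stretch_start
                    completeness = "5prime_partial" if is_stop else "internal"
                else:
                    start = None
                    completeness = ""
                if start is not None and (stretch_end - start) // 3 >= min_aa:
                    yield start, stretch_end, completeness
            if at_end:
                break
            has_upstream_stop = True
            stretch_start = pos + 3
        pos += 3


def find_orfs(
    record: SequenceRecord,
    min_aa: int = 100,
    separator: str = DEFAULT_SEPARATOR,
) -> list[CdsRecord]:
    """Detect ORFs of >= ``min_aa`` amino acids in all six frames.

    One ORF per stop-free stretch at most (no nested sub-ORFs).  Output is
    sorted by amino-acid length descending, then (strand, start), and CDS
    ids are numbered in that order.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    L = len(record.seq)
    found = []
    for strand in "+-":
        coding = record.seq if strand == "+" else reverse_complement(record.seq)
        for frame in range(3):
            for s, e, completeness in _stretch_orfs(coding, frame, min_aa):
                if strand == "+":
                    fwd_start, fwd_end = s, e
                else:
                    fwd_start, fwd_end = L - e, L - s
                found.append(
                    dict(
                        strand=strand,
                        frame=frame,
                        start=fwd_start,
                        end=fwd_end,
                        aa_len=(e - s) // 3,
                        nt_seq=coding[s:e],
                        completeness=completeness,
                    )
                )
    found.sort(key=lambda d: (-d["aa_len"], d["strand"], d["start"]))
    return [
        CdsRecord(
            cds_id=f"{record.id}{separator}cds{k}",
            transcript_id=record.id,
            source=record.source,
            **d,
        )
        for k, d in enumerate(found, start=1)
    ]


def extract_cds(
    records: Sequence[SequenceRecord],
    min_aa: int = 100,
    separator: str = DEFAULT_SEPARATOR,
) -> list[CdsRecord]:
    """Concatenate :func:`find_orfs` over all records.

    A transcript may yield zero, one or several CDSs; ids are numbered per
    transcript in output order.
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate transcript ids")
    out: list[CdsRecord] = []
    for rec in records:
        out.extend(find_orfs(rec, min_aa=min_aa, separator=separator))
    return out


def cds_counts(cds_records: Iterable[CdsRecord]) -> dict[str, int]:
    """Number of CDSs per transcript id."""
    counts: dict[str, int] = {}
    for cds in cds_records:
        counts[cds.transcript_id] = counts.get(cds.transcript_id, 0) + 1
    return counts


def write_cds_fasta(cds_records: Iterable[CdsRecord], path, width: int = 80) -> None:
    """Write CDS nucleotide FASTA; the description carries strand,
    1-based inclusive coordinates and completeness."""
    with open(path, "w") as fh:
        for cds in cds_records:
            fh.write(
                f">{cds.cds_id} {cds.transcript_id}:{cds.start + 1}-{cds.end}"
                f"({cds.strand}) {cds.completeness} len_aa={cds.aa_len}\n"
            )
            for i in range(0, len(cds.nt_seq), width):
                fh.write(cds.nt_seq[i : i + width] + "\n")


def write_peptide_fasta(cds_records: Iterable[CdsRecord], path, width: int = 80) -> None:
    """Write the translated CDSs as a peptide FASTA (no stop residue)."""
    with open(path, "w") as fh:
        for cds in cds_records:
            aa = translate(cds.nt_seq)
            fh.write(f">{cds.cds_id} {cds.completeness} len_aa={cds.aa_len}\n")
            for i in range(0, len(aa), width):
                fh.write(aa[i : i + width] + "\n")
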