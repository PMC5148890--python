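"""Independent oracles used by the test suite.

Everything here is deliberately written *without* reusing the package's
algorithmic code paths: a pure-Python affine-gap Smith-Waterman, a naive
six-frame ORF scan built on Biopython translation, a brute-force substring
containment filter, an independently coded greedy clustering loop, and a
manifest-expectation calculator for synthetic fixtures.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Sequence

from Bio.Seq import Seq

from txconsensus.clustering import local_align
from txconsensus.seqio import SequenceRecord

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 2, -3, -5, -2
NEG = float("-inf")


def rc(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# brute-force affine local alignment (Gotoh, full DP, no shortcuts)
# ---------------------------------------------------------------------------

@dataclass
class DPSummary:
    score: int
    identity: float
    cov_short: float
    cov_long: float
    strand: str


def _score(x: str, y: str) -> int:
    return MATCH if (x == y and x != "N") else MISMATCH


def _sw_one_strand(a: str, b: str):
    """Full Smith-Waterman with affine gaps; returns (score, identity,
    cov_a, cov_b) of the best local alignment (traceback prefers the
    lowest (i, j) end cell, diagonal moves first)."""
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i][j] = max(M[i - 1][j] + GAP_OPEN, Ix[i - 1][j] + GAP_EXTEND,
                           Iy[i - 1][j] + GAP_OPEN)
            Iy[i][j] = max(M[i][j - 1] + GAP_OPEN, Iy[i][j - 1] + GAP_EXTEND,
                           Ix[i][j - 1] + GAP_OPEN)
            diag = max(0.0, M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = diag + _score(a[i - 1], b[j - 1])
            if M[i][j] > best:
                best, bi, bj = M[i][j], i, j
    if best <= 0:
        return 0, 0.0, 0.0, 0.0
    # traceback from the best M cell
    i, j, state = bi, bj, "M"
    matches = columns = 0
    end_i, end_j = bi, bj
    while True:
        if state == "M":
            columns += 1
            if a[i - 1] == b[j - 1] and a[i - 1] != "N":
                matches += 1
            prev = max(0.0, M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            i, j = i - 1, j - 1
            if prev == 0.0:
                break
            if prev == M[i][j]:
                state = "M"
            elif prev == Ix[i][j]:
                state = "Ix"
            else:
                state = "Iy"
        elif state == "Ix":
            columns += 1
            val = Ix[i][j]
            if val == M[i - 1][j] + GAP_OPEN:
                state = "M"
            elif val == Ix[i - 1][j] + GAP_EXTEND:
                state = "Ix"
            else:
                state = "Iy"
            i -= 1
        else:
            columns += 1
            val = Iy[i][j]
            if val == M[i][j - 1] + GAP_OPEN:
                state = "M"
            elif val == Iy[i][j - 1] + GAP_EXTEND:
                state = "Iy"
            else:
                state = "Ix"
            j -= 1
    span_a, span_b = end_i - i, end_j - j
    return int(best), matches / columns, span_a / len(a), span_b / len(b)


def sw_local_align(a: str, b: str, both_strands: bool = True) -> DPSummary:
    """Exhaustive-DP oracle mirroring the contract of clustering.local_align."""
    results = []
    for strand, oriented in (("+", b), ("-", rc(b))):
        score, identity, cov_a, cov_b = _sw_one_strand(a, oriented)
        if len(a) <= len(b):
            cov_short, cov_long = cov_a, cov_b
        else:
            cov_short, cov_long = cov_b, cov_a
        results.append(DPSummary(score, identity, cov_short, cov_long, strand))
        if not both_strands:
            break
    return max(results, key=lambda r: (r.score, r.strand == "+"))


# ---------------------------------------------------------------------------
# reference greedy clustering (full kernel on every comparison)
# ---------------------------------------------------------------------------

def reference_greedy(records: Sequence[SequenceRecord], c: float, aS: float,
                     aL: float, both_strands: bool = True) -> list[list[str]]:
    """Greedy clustering with no prefilter and no exact-match shortcut:
    every (record, representative) pair goes through the full alignment
    kernel.  Returns member-id lists, representative first."""
    eps = 1e-9
    ordered = sorted(records, key=lambda r: (-len(r.seq), r.id))
    clusters: list[list[str]] = []
    reps: list[SequenceRecord] = []
    for rec in ordered:
        for i, rep in enumerate(reps):
            s = local_align(rep, rec, both_strands=both_strands)
            if (s.identity >= c - eps and s.cov_short >= aS - eps
                    and s.cov_long >= aL - eps):
                clusters[i].append(rec.id)
                break
        else:
            clusters.append([rec.id])
            reps.append(rec)
    return clusters


# ---------------------------------------------------------------------------
# brute-force both-strand exact-substring filter
# ---------------------------------------------------------------------------

def substring_filter(records: Sequence[SequenceRecord],
                     aL: float = 0.005) -> list[str]:
    """Ids retained after removing every record that is an exact (N-free)
    substring, on either strand, of an already retained longer record."""
    retained: list[SequenceRecord] = []
    for rec in sorted(records, key=lambda r: (-len(r.seq), r.id)):
        removed = False
        if "N" not in rec.seq:
            for other in retained:
                if len(rec.seq) / len(other.seq) < aL - 1e-9:
                    continue
                if rec.seq in other.seq or rc(rec.seq) in other.seq:
                    removed = True
                    break
        if not removed:
            retained.append(rec)
    return [r.id for r in retained]


# ---------------------------------------------------------------------------
# naive six-frame ORF scan
# ---------------------------------------------------------------------------

def naive_orf_scan(seq: str, min_aa: int = 100) -> set[tuple]:
    """Translate all six frames with Biopython and scan stop-to-stop.

    Returns {(strand, start, end, aa_len, completeness)} with coordinates on
    the forward strand, stop codon excluded.  A codon containing N is never
    a stop; the reported ORF starts at the first ATG of a stretch, or at the
    stretch start if the stretch touches the 5' boundary of its frame.
    """
    out = set()
    L = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else rc(seq)
        for frame in range(3):
            codons = [s[p:p + 3] for p in range(frame, L - 2, 3)]
            is_stop = [
                ("N" not in cd) and str(Seq(cd).translate()) == "*" for cd in codons
            ]
            start_codon = 0
            upstream_stop = False
            for k in range(len(codons) + 1):
                at_end = k == len(codons)
                if at_end or is_stop[k]:
                    if k > start_codon:
                        atg = next(
                            (x for x in range(start_codon, k) if codons[x] == "ATG"),
                            None,
                        )
                        if atg is not None:
                            first = atg
                            completeness = "complete" if not at_end else "3prime_partial"
                        elif not upstream_stop:
                            first = start_codon
                            completeness = "5prime_partial" if not at_end else "internal"
                        else:
                            first = None
                            completeness = ""
                        if first is not None and k - first >= min_aa:
                            lo = frame + 3 * first
                            hi = frame + 3 * k
                            if strand == "-":
                                lo, hi = L - hi, L - lo
                            out.add((strand, lo, hi, k - first, completeness))
                    upstream_stop = True
                    start_codon = k + 1
    return out


# ---------------------------------------------------------------------------
# manifest expectations for synthetic fixtures
# ---------------------------------------------------------------------------

@dataclass
class ExpectedConsensus:
    n_unicds: int
    n_final: int
    n_multi_cds: int
    n_redundant_cds: int
    categories: dict[int, int]  # category -> count
    extensions: dict[str, tuple[int, int]]  # label -> (n_extended, cumulated bp)
    step5: dict[str, tuple[int, int]]  # label -> (n_in, n_retained)
    missing_original_ids: set[str]
    invented_final_ids: set[str]  # harmonized transcript ids


# category convention for exactly three assemblers [A, B, C]
def _category(present: frozenset, labels: Sequence[str]) -> int:
    A, B, C = labels
    table = {
        frozenset({A, B, C}): 1,
        frozenset({A, B}): 2,
        frozenset({A, C}): 3,
        frozenset({B, C}): 4,
        frozenset({A}): 5,
        frozenset({C}): 6,
        frozenset({B}): 7,
    }
    return table[present]


def expected_consensus(manifest, separator: str = "|") -> ExpectedConsensus:
    """Compute every downstream pipeline count directly from planted fates."""
    labels = list(manifest.labels)
    categories: dict[int, int] = {}
    extensions = {lab: [0, 0] for lab in labels}
    step5 = {}
    missing: set[str] = set()
    invented: set[str] = set()
    n_unicds = 0

    for gene in manifest.genes:
        contributors = {
            lab: f.cds_len
            for lab, f in gene.fates.items()
            if f.fate == "present" and f.cds_len > 0
        }
        if not contributors:
            missing.add(gene.gene_id)
            continue
        n_unicds += 1
        cat = _category(frozenset(contributors), labels)
        categories[cat] = categories.get(cat, 0) + 1
        rep_len = max(contributors.values())
        for lab, cds_len in contributors.items():
            if cds_len < rep_len:
                extensions[lab][0] += 1
                extensions[lab][1] += rep_len - cds_len

    for art in manifest.artifacts:
        if art.has_orf:
            n_unicds += 1
            cat = _category(frozenset({art.label}), labels)
            categories[cat] = categories.get(cat, 0) + 1
            invented.add(f"{art.label}{separator}{art.artifact_id}")

    for lab in labels:
        n_in = n_ret = 0
        for gene in manifest.genes:
            f = gene.fates[lab]
            if f.fate == "present":
                n_in += len(f.output_ids)
                n_ret += 1
        n_art = sum(1 for a in manifest.artifacts if a.label == lab)
        step5[lab] = (n_in + n_art, n_ret + n_art)

    return ExpectedConsensus(
        n_unicds=n_unicds,
        n_final=n_unicds,  # exactly one CDS per planted transcript
        n_multi_cds=0,
        n_redundant_cds=0,
        categories=categories,
        extensions={lab: tuple(v) for lab, v in extensions.items()},
        step5=step5,
        missing_original_ids=missing,
        invented_final_ids=invented,
    )


# ---------------------------------------------------------------------------
# random-instance factory for clustering equivalence tests
# ---------------------------------------------------------------------------

def random_instance(rng: random.Random, n_max: int = 12,
                    long_tail: bool = False) -> list[SequenceRecord]:
    """A family of related and unrelated sequences: a few 'genes' plus
    mutated / truncated / reverse-complemented copies of them."""
    records = []
    n_genes = rng.randint(2, 4)
    genes = []
    for g in range(n_genes):
        length = rng.randint(1500, 2000) if (long_tail and g == 0) else rng.randint(100, 400)
        genes.append("".join(rng.choice("ACGT") for _ in range(length)))
    idx = 0
    n_total = rng.randint(max(4, n_genes), n_max)
    while idx < n_total:
        gene = rng.choice(genes)
        kind = rng.random()
        if kind < 0.25:
            seq = gene
        elif kind < 0.5:  # mutated copy
            chars = list(gene)
            for _ in range(rng.randint(1, max(1, len(gene) // 40))):
                p = rng.randrange(len(chars))
                chars[p] = rng.choice([b for b in "ACGT" if b != chars[p]])
            seq = "".join(chars)
        elif kind < 0.75:  # truncation / substring
            n = rng.randint(min(50, len(gene)), len(gene))
            off = rng.randint(0, len(gene) - n)
            seq = gene[off:off + n]
        else:  # unrelated
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(80, 300)))
        if rng.random() < 0.3:
            seq = rc(seq)
        records.append(SequenceRecord(id=f"s{idx:03d}", seq=seq))
        idx += 1
    return records


def clusterset_as_lists(cluster_set) -> list[list[str]]:
    return [c.member_ids for c in cluster_set.clusters]
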