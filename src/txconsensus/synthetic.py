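"""Synthetic truth transcriptomes and mock assembler outputs.

The generator plants a known coding transcriptome (one verified ORF per
transcript, flanked by in-frame stop codons so the planted ORF is the unique
maximal one) and derives per-assembler mock outputs with controlled
imperfections:

* duplication — exact copies or exact substrings (what intra-assembly
  de-duplication must remove),
* fragmentation — truncation from one end (what drives CDS extensions),
* substitution error — emulating sequencing/assembly error at a per-base
  rate (what the 98%-identity clustering step must absorb),
* dropout — transcripts an assembler misses (what the reference-recovery
  comparison must flag), biased toward low-coverage transcripts,
* artifact transcripts — random sequences unique to one assembler, with or
  without a planted ORF (what single-assembler categories flag).

Every planted fate is recorded in a manifest and *realized exactly*, so the
manifest serves as an exact oracle for every downstream pipeline count.
Exactness is engineered, not hoped for:

* substitutions never create an in-frame stop and never touch the start
  codon, the stop codon, or the planted upstream in-frame stop;
* each copy receives a fixed substitution budget, floor(rate * length),
  placed at most one per equal-length window (stratified), so local error
  density never exceeds the global rate.  With the default ORF fraction
  (>= 0.5 of the transcript) this makes pairwise CDS divergence between two
  copies provably < 2%, i.e. the 98%-identity clustering threshold is met
  deterministically, not just in expectation;
* no substitutions fall within the terminal bases of a planted CDS or
  within +-10 nt of any planned truncation site of the same gene (in *any*
  copy), so the best local alignment between two copies is the full gapless
  overlap and coverage of the shorter CDS is exactly 1.0 — planted copies
  always satisfy the strict aS=1.00 setting.

Substitution-only errors (no indels) keep pairwise identity linear in the
error rate; indels are deliberately out of the default model.

The same seed always produces byte-identical output (one stated PRNG,
no environment-dependent ordering).
"""

from __future__ import annotations

import dataclasses
import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .orf import STOP_CODONS, find_orfs
from .seqio import SequenceRecord, write_fasta

__all__ = [
    "GeneFate",
    "GeneInfo",
    "ArtifactInfo",
    "AssemblyPlan",
    "TruthManifest",
    "default_study_plans",
    "generate_truth",
    "generate_assemblies",
    "write_fixture",
]

_BASES = "ACGT"
_NON_STOP_CODONS = sorted(
    {a + b + c for a in _BASES for b in _BASES for c in _BASES} - STOP_CODONS
)
_MAX_ATTEMPTS = 200


@dataclass
class GeneFate:
    """Realized fate of one gene in one assembler's output."""

    fate: str  # "present" or "dropped"
    output_ids: list[str] = field(default_factory=list)
    truncated_to: Optional[int] = None  # retained transcript length, nt
    n_substitutions: int = 0
    duplicated: Optional[str] = None  # "copy" | "substring"
    cds_len: int = 0  # expected CDS length (nt) of the emitted copy; 0 = none
    coverage_of_original: float = 0.0  # emitted length / original length


@dataclass
class GeneInfo:
    gene_id: str
    length: int
    orf_start: int  # 0-based, half-open, stop codon excluded
    orf_end: int
    strand: str
    cds_len: int
    paralog_family: int
    coverage: float
    fates: dict[str, GeneFate] = field(default_factory=dict)


@dataclass
class ArtifactInfo:
    artifact_id: str
    label: str
    length: int
    has_orf: bool
    cds_len: int


@dataclass(frozen=True)
class AssemblyPlan:
    """Planned imperfections of one mock assembler output."""

    dropout_rate: float = 0.0
    dup_rate: float = 0.0
    fragment_rate: float = 0.0
    # fragments keep > 50% of the transcript so a truncated-but-present gene
    # still counts as recovered under the standard >= 50%-coverage rule
    fragment_fraction_range: tuple[float, float] = (0.55, 0.9)
    error_rate: float = 0.0
    n_artifacts: int = 0
    artifact_orf: bool = False
    artifact_length_range: tuple[int, int] = (400, 1200)
    truncate_end: str = "3prime"  # or "5prime"

    def __post_init__(self) -> None:
        for name in ("dropout_rate", "dup_rate", "fragment_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.truncate_end not in ("3prime", "5prime"):
            raise ValueError("truncate_end must be '3prime' or '5prime'")


@dataclass
class TruthManifest:
    seed: int
    min_aa: int
    genes: list[GeneInfo]
    labels: list[str] = field(default_factory=list)
    artifacts: list[ArtifactInfo] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def coverage_table(self) -> dict[str, float]:
        return {g.gene_id: g.coverage for g in self.genes}


def default_study_plans(
    labels: Sequence[str] = ("CLC", "IDBA_tran", "Trinity"),
) -> dict[str, AssemblyPlan]:
    """The default study conditions for a three-assembler experiment.

    Every assembler misses 10% of transcripts, truncates 20% and carries
    0.5% substitution error; the last (Trinity-like) assembler additionally
    duplicates 30% of its transcripts — single-transcript graph processing
    makes that assembler family by far the most internally redundant — and
    each assembler emits 5 artifact transcripts, ORF-bearing only in the
    Trinity-like output.
    """
    plans = {}
    for i, label in enumerate(labels):
        last = i == len(labels) - 1
        plans[label] = AssemblyPlan(
            dropout_rate=0.1,
            fragment_rate=0.2,
            error_rate=0.005,
            dup_rate=0.3 if last else 0.0,
            n_artifacts=5,
            artifact_orf=last,
        )
    return plans


# ---------------------------------------------------------------------------
# truth generation
# ---------------------------------------------------------------------------

def _random_utr(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(n))


def _random_orf_body(rng: random.Random, aa: int) -> str:
    """ATG plus aa-1 random non-stop codons (no stop codon appended)."""
    return "ATG" + "".join(rng.choice(_NON_STOP_CODONS) for _ in range(aa - 1))


def _build_transcript(
    rng: random.Random, length: int, aa: int, orf_body: Optional[str] = None
) -> tuple[str, int, int]:
    """Assemble utr5 + in-frame stop + ORF + stop + utr3; returns
    (sequence, orf_start, orf_end)."""
    overhead = 3 * aa + 6  # upstream stop + ORF + stop
    utr_total = length - overhead
    u5 = rng.randint(0, utr_total)
    u3 = utr_total - u5
    body = orf_body if orf_body is not None else _random_orf_body(rng, aa)
    stop = rng.choice(sorted(STOP_CODONS))
    upstream_stop = rng.choice(sorted(STOP_CODONS))
    seq = _random_utr(rng, u5) + upstream_stop + body + stop + _random_utr(rng, u3)
    orf_start = u5 + 3
    return seq, orf_start, orf_start + 3 * aa


def _verified_transcript(
    rng: random.Random,
    gene_id: str,
    length: int,
    aa: int,
    min_aa: int,
    orf_body: Optional[str] = None,
) -> tuple[SequenceRecord, int, int]:
    """Build a transcript whose planted ORF is the unique one found."""
    for _ in range(_MAX_ATTEMPTS):
        body = orf_body  # paralogs reuse a mutated body verbatim
        seq, s, e = _build_transcript(rng, length, aa, body)
        rec = SequenceRecord(id=gene_id, seq=seq, source="truth")
        orfs = find_orfs(rec, min_aa=min_aa)
        if (
            len(orfs) == 1
            and orfs[0].start == s
            and orfs[0].end == e
            and orfs[0].strand == "+"
            and orfs[0].completeness == "complete"
        ):
            return rec, s, e
    raise RuntimeError(f"could not realize a clean transcript for {gene_id}")


def _mutate_orf_body(
    rng: random.Random, body: str, rate: float
) -> tuple[str, int]:
    """Substitute bases of an ORF body at `rate`, keeping the ATG intact and
    never creating a stop codon.  Returns (new body, substitutions made)."""
    seq = list(body)
    n_subs = 0
    for pos in range(3, len(seq)):  # never touch the start codon
        if rng.random() >= rate:
            continue
        codon_start = 3 * (pos // 3)
        alternatives = [b for b in _BASES if b != seq[pos]]
        rng.shuffle(alternatives)
        for alt in alternatives:
            codon = seq[codon_start:codon_start + 3]
            codon[pos - codon_start] = alt
            if "".join(codon) not in STOP_CODONS:
                seq[pos] = alt
                n_subs += 1
                break
    return "".join(seq), n_subs


def generate_truth(
    n_genes: int = 50,
    length_range: tuple[int, int] = (600, 2500),
    orf_fraction_range: tuple[float, float] = (0.5, 0.85),
    n_paralog_pairs: int = 0,
    paralog_divergence: float = 0.03,
    min_aa: int = 100,
    seed: int = 0,
) -> tuple[list[SequenceRecord], TruthManifest]:
    """Generate a truth transcriptome with one planted ORF per transcript.

    The first ``2 * n_paralog_pairs`` genes form paralog pairs whose ORFs
    differ by per-base substitutions at ``paralog_divergence``.  Per-gene
    fold-coverages are drawn log-normally (median ~25x) so that a realistic
    minority of transcripts falls below the usual 10x recovery horizon.
    """
    if length_range[0] < 3 * (min_aa + 2):
        raise ValueError("minimum length cannot accommodate the minimum ORF")
    if not 0.0 <= paralog_divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    if 2 * n_paralog_pairs > n_genes:
        raise ValueError("more paralog pairs than genes")
    rng = random.Random(seed)
    records: list[SequenceRecord] = []
    genes: list[GeneInfo] = []
    pending_paralog: Optional[GeneInfo] = None
    for i in range(n_genes):
        gene_id = f"gene{i + 1:04d}"
        if pending_paralog is not None:
            # second member of a pair: same length/ORF size, diverged body
            template = pending_paralog
            src = next(r for r in records if r.id == template.gene_id)
            body = src.seq[template.orf_start : template.orf_end]
            body, _ = _mutate_orf_body(rng, body, paralog_divergence)
            rec, s, e = _verified_transcript(
                rng, gene_id, template.length, template.cds_len // 3, min_aa, body
            )
            family = template.paralog_family
            pending_paralog = None
        else:
            length = rng.randint(*length_range)
            frac = rng.uniform(*orf_fraction_range)
            aa = max(min_aa, (int(frac * length) - 6) // 3)
            aa = min(aa, (length - 6) // 3)
            rec, s, e = _verified_transcript(rng, gene_id, length, aa, min_aa)
            family = i
        coverage = round(math.exp(rng.gauss(3.2, 0.9)), 1)
        info = GeneInfo(
            gene_id=gene_id,
            length=len(rec.seq),
            orf_start=s,
            orf_end=e,
            strand="+",
            cds_len=e - s,
            paralog_family=family,
            coverage=coverage,
        )
        records.append(rec)
        genes.append(info)
        if i < 2 * n_paralog_pairs and i % 2 == 0:
            pending_paralog = info
    manifest = TruthManifest(seed=seed, min_aa=min_aa, genes=genes)
    return records, manifest


# ---------------------------------------------------------------------------
# mock assembler outputs
# ---------------------------------------------------------------------------

def _expected_cds_after_truncation(
    seq: str, orf_start: int, orf_end: int, kept: tuple[int, int], min_aa: int
) -> int:
    """Expected CDS length (nt) after keeping seq[kept[0]:kept[1]].

    3'-end truncation leaves a prefix of the CDS (ATG onward, codon-floored);
    5'-end truncation restarts the CDS at the first surviving in-frame ATG
    when one exists, else at the frame-aligned stretch start (5'-partial).
    """
    lo, hi = kept
    if lo <= orf_start and hi >= orf_end:
        return orf_end - orf_start
    if lo <= orf_start:  # 3' truncation into the ORF
        cds = 3 * ((min(hi, orf_end) - orf_start) // 3)
    else:  # 5' truncation into the ORF
        first = None
        for p in range(orf_start, orf_end, 3):
            if p >= lo and seq[p : p + 3] == "ATG":
                first = p
                break
        if first is None:
            # 5'-partial: stretch starts at the first in-frame position >= lo
            first = lo + ((orf_start - lo) % 3)
        cds = 3 * ((min(hi, orf_end) - first) // 3)
    return cds if cds >= 3 * min_aa else 0


_CUT_HALO = 10  # no substitutions within this many nt of a truncation site
_TERMINAL_GUARD = 6  # substitution-free bases at each end of a planted CDS


def _protected_positions(gene: GeneInfo, cut_sites: set[int]) -> set[int]:
    """Original-coordinate positions no copy of this gene may mutate."""
    protected = set(range(gene.orf_start - 3, gene.orf_start + _TERMINAL_GUARD))
    protected |= set(range(gene.orf_end - _TERMINAL_GUARD, gene.orf_end + 3))
    for t in cut_sites:
        protected |= set(range(max(0, t - _CUT_HALO), t + _CUT_HALO))
    return protected


def _stratified_substitute(
    rng: random.Random,
    seq: str,
    rate: float,
    offset: int,
    gene: GeneInfo,
    protected: set[int],
) -> tuple[str, int]:
    """Place floor(rate*len) substitutions, at most one per equal-length
    window, skipping protected positions and never creating in-frame stops.
    ``offset`` maps local positions to original transcript coordinates."""
    n_target = int(rate * len(seq))
    if n_target == 0:
        return seq, 0
    chars = list(seq)
    window = len(seq) / n_target
    n_subs = 0
    for i in range(n_target):
        lo = int(i * window)
        hi = max(lo + 1, int((i + 1) * window))
        for _ in range(10):  # a protected/stop-locked window may stay clean
            pos = rng.randrange(lo, hi)
            orig_pos = pos + offset
            if orig_pos in protected:
                continue
            alternatives = [b for b in _BASES if b != chars[pos]]
            rng.shuffle(alternatives)
            placed = False
            if gene.orf_start <= orig_pos < gene.orf_end:
                codon_start = pos - (orig_pos - gene.orf_start) % 3
                for alt in alternatives:
                    codon = chars[codon_start : codon_start + 3]
                    if len(codon) < 3 or codon_start < 0:
                        break  # codon cut by truncation; leave it alone
                    codon[pos - codon_start] = alt
                    if "".join(codon) not in STOP_CODONS:
                        chars[pos] = alt
                        placed = True
                        break
            else:
                chars[pos] = alternatives[0]
                placed = True
            if placed:
                n_subs += 1
                break
    return "".join(chars), n_subs


def _pick_cut(
    rng: random.Random,
    truth_seq: str,
    gene: GeneInfo,
    plan: AssemblyPlan,
    min_aa: int,
) -> int:
    """Choose a truncation length whose CDS outcome is exactly predictable.

    Removing sequence can expose a new boundary-abutting (partial) ORF on
    the opposite strand; such cut positions are rejected here, against the
    unmutated truth sequence, so every planned truncation stays an exact
    manifest fate."""
    L = len(truth_seq)
    for _ in range(_MAX_ATTEMPTS):
        f = rng.uniform(*plan.fragment_fraction_range)
        t = max(3 * min_aa + 9, round(f * L))
        kept = (0, t) if plan.truncate_end == "3prime" else (L - t, L)
        expected = _expected_cds_after_truncation(
            truth_seq, gene.orf_start, gene.orf_end, kept, min_aa
        )
        seq = truth_seq[kept[0] : kept[1]]
        orfs = find_orfs(SequenceRecord(id="tmp", seq=seq), min_aa=min_aa)
        if (expected == 0 and not orfs) or (
            expected > 0
            and len(orfs) == 1
            and len(orfs[0].nt_seq) == expected
            and orfs[0].strand == "+"
        ):
            return t
    raise RuntimeError(f"no clean truncation point found for {gene.gene_id}")


def _realize_copy(
    rng: random.Random,
    truth_seq: str,
    gene: GeneInfo,
    plan: AssemblyPlan,
    cut: Optional[int],
    protected: set[int],
    min_aa: int,
) -> tuple[str, GeneFate]:
    """Apply truncation + substitutions, re-verifying that the emitted copy
    carries exactly the CDS content the manifest promises."""
    L = len(truth_seq)
    if cut is not None:
        kept = (0, cut) if plan.truncate_end == "3prime" else (L - cut, L)
    else:
        kept = (0, L)
    expected = _expected_cds_after_truncation(
        truth_seq, gene.orf_start, gene.orf_end, kept, min_aa
    )
    base = truth_seq[kept[0] : kept[1]]
    for _ in range(_MAX_ATTEMPTS):
        seq, n_subs = (
            _stratified_substitute(rng, base, plan.error_rate, kept[0], gene, protected)
            if plan.error_rate > 0
            else (base, 0)
        )
        orfs = find_orfs(SequenceRecord(id="tmp", seq=seq), min_aa=min_aa)
        ok = (
            (expected == 0 and not orfs)
            or (
                expected > 0
                and len(orfs) == 1
                and len(orfs[0].nt_seq) == expected
                and orfs[0].strand == "+"
            )
        )
        if ok:
            fate = GeneFate(
                fate="present",
                truncated_to=(kept[1] - kept[0]) if cut is not None else None,
                n_substitutions=n_subs,
                cds_len=expected,
                coverage_of_original=(kept[1] - kept[0]) / L,
            )
            return seq, fate
    raise RuntimeError(f"could not realize copy of {gene.gene_id}")


def _orf_free_sequence(rng: random.Random, length: int, min_aa: int) -> str:
    for _ in range(_MAX_ATTEMPTS):
        seq = _random_utr(rng, length)
        if not find_orfs(SequenceRecord(id="tmp", seq=seq), min_aa=min_aa):
            return seq
    raise RuntimeError("could not generate an ORF-free artifact")


def generate_assemblies(
    truth: Sequence[SequenceRecord],
    manifest: TruthManifest,
    plans: Mapping[str, AssemblyPlan],
    seed: int = 0,
) -> dict[str, list[SequenceRecord]]:
    """Derive mock assembler outputs from the truth per plan.

    Each label consumes an independent PRNG stream (derived from ``seed``
    and the label position) so adding an assembler does not perturb the
    others.  Realized fates are recorded into ``manifest``.
    """
    truth_by_id = {r.id: r for r in truth}
    manifest.labels = list(plans.keys())
    manifest.artifacts = []
    assemblies: dict[str, list[SequenceRecord]] = {}

    # planning pass: decide dropouts and truncation sites for every label
    # first, so substitution-protected zones around *all* cut sites of a gene
    # are known before any copy is realized
    dropped_by_label: dict[str, set[str]] = {}
    cut_by_label: dict[str, dict[str, int]] = {}
    cut_sites: dict[str, set[int]] = {g.gene_id: set() for g in manifest.genes}
    for label_idx, (label, plan) in enumerate(plans.items()):
        rng = random.Random(seed * 1_000_003 + 2 * label_idx + 1)
        n_drop = round(plan.dropout_rate * len(manifest.genes))
        dropped: set[str] = set()
        pool = [g.gene_id for g in manifest.genes]
        w = [1.0 / max(g.coverage, 0.1) for g in manifest.genes]
        for _ in range(n_drop):
            pick = rng.choices(range(len(pool)), weights=w, k=1)[0]
            dropped.add(pool.pop(pick))
            w.pop(pick)
        surviving = [g for g in manifest.genes if g.gene_id not in dropped]
        n_frag = round(plan.fragment_rate * len(surviving))
        cuts: dict[str, int] = {}
        for gene in rng.sample(surviving, n_frag):
            t = _pick_cut(
                rng, truth_by_id[gene.gene_id].seq, gene, plan, manifest.min_aa
            )
            cuts[gene.gene_id] = t
            site = t if plan.truncate_end == "3prime" else gene.length - t
            cut_sites[gene.gene_id].add(site)
        dropped_by_label[label] = dropped
        cut_by_label[label] = cuts

    protected = {
        g.gene_id: _protected_positions(g, cut_sites[g.gene_id])
        for g in manifest.genes
    }

    for label_idx, (label, plan) in enumerate(plans.items()):
        rng = random.Random(seed * 1_000_003 + 2 * label_idx + 2)
        records: list[SequenceRecord] = []
        dropped = dropped_by_label[label]
        cuts = cut_by_label[label]

        for gene in manifest.genes:
            if gene.gene_id in dropped:
                gene.fates[label] = GeneFate(fate="dropped")
                continue
            seq, fate = _realize_copy(
                rng,
                truth_by_id[gene.gene_id].seq,
                gene,
                plan,
                cut=cuts.get(gene.gene_id),
                protected=protected[gene.gene_id],
                min_aa=manifest.min_aa,
            )
            fate.output_ids = [gene.gene_id]
            records.append(SequenceRecord(id=gene.gene_id, seq=seq))
            if rng.random() < plan.dup_rate:
                kind = rng.choice(["copy", "substring"])
                dup_id = f"{gene.gene_id}_dup"
                if kind == "copy":
                    dup_seq = seq
                else:
                    frac = rng.uniform(0.3, 0.9)
                    n = max(30, round(frac * len(seq)))
                    off = rng.randint(0, len(seq) - n)
                    dup_seq = seq[off : off + n]
                fate.duplicated = kind
                fate.output_ids.append(dup_id)
                records.append(SequenceRecord(id=dup_id, seq=dup_seq))
            gene.fates[label] = fate

        for a_idx in range(plan.n_artifacts):
            art_id = f"artifact{a_idx + 1:03d}"
            length = rng.randint(*plan.artifact_length_range)
            if plan.artifact_orf:
                aa = max(manifest.min_aa, (int(0.7 * length) - 6) // 3)
                rec, s, e = _verified_transcript(
                    rng, art_id, length, aa, manifest.min_aa
                )
                cds_len = e - s
                records.append(rec)
            else:
                records.append(
                    SequenceRecord(
                        id=art_id, seq=_orf_free_sequence(rng, length, manifest.min_aa)
                    )
                )
                cds_len = 0
            manifest.artifacts.append(
                ArtifactInfo(
                    artifact_id=art_id,
                    label=label,
                    length=length,
                    has_orf=plan.artifact_orf,
                    cds_len=cds_len,
                )
            )
        assemblies[label] = records

    return assemblies


def write_fixture(
    outdir: str | Path,
    truth: Sequence[SequenceRecord],
    assemblies: Mapping[str, Sequence[SequenceRecord]],
    manifest: TruthManifest,
) -> None:
    """Write truth FASTA, per-assembler FASTAs, manifest JSON, coverage TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(truth, outdir / "truth.fasta")
    for label, records in assemblies.items():
        write_fasta(records, outdir / f"{label}.fasta")
    manifest.to_json(outdir / "manifest.json")
    with open(outdir / "coverage.tsv", "w") as fh:
        for gene in manifest.genes:
            fh.write(f"{gene.gene_id}\t{gene.coverage}\n")
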