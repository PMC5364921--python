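"""Sequence-level quality control for paired amplicon reads.

Implements the filters a COI metabarcoding pipeline applies before OTU
clustering: ungapped pair merging with a mismatch cap, expected-error
filtering from Phred scores, dual-index demultiplexing with a tag-jump guard
(identical index required on both ends), homopolymer and ambiguity screens, a
stop-codon screen under the invertebrate mitochondrial code (translation
table 5), exact dereplication, greedy abundance-ranked preclustering, and
singleton removal.

Every read pair ends in exactly one bin — the merged/passed bin or one named
rejection reason — so the per-stage ledger always sums to the input count.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "ReadPair",
    "FilterRules",
    "UniqueSequence",
    "MergeResult",
    "merge_pair",
    "expected_errors",
    "demultiplex",
    "content_filters",
    "stop_codon_screen",
    "dereplicate",
    "precluster",
    "remove_singletons",
    "reverse_complement",
    "iupac_match",
    "read_fastq_pairs",
    "write_fasta_with_sizes",
    "run_read_qc",
]

# IUPAC degeneracies; inosine (I) read as fully degenerate.
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "I": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNI", "TGCAYRSWMKVHDBNI")



def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(pattern: str, seq: str) -> bool:
    """True if ``seq`` matches ``pattern`` base-by-base under IUPAC semantics."""
    if len(pattern) != len(seq):
        return False
    return all(b in _IUPAC.get(p, "") for p, b in zip(pattern, seq))


@dataclass(frozen=True)
class ReadPair:
    """A paired-end read: sequences plus per-base Phred qualities."""

    id: str
    fwd: str
    fwd_qual: tuple[int, ...]
    rev: str
    rev_qual: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.fwd) != len(self.fwd_qual) or len(self.rev) != len(self.rev_qual):
            raise ValueError(f"{self.id}: sequence and quality lengths differ")
        for q in (*self.fwd_qual, *self.rev_qual):
            if not 0 <= q <= 93:
                raise ValueError(f"{self.id}: Phred value {q} outside [0, 93]")


@dataclass(frozen=True)
class FilterRules:
    """Thresholds for the QC stages.

    Defaults are the pipeline's standard settings: at most 5 mismatches and 0
    gaps in the merge overlap, at most 1 expected error in the merged read,
    6-base sample indices, homopolymers longer than 8 bp rejected, ambiguous
    bases rejected, invertebrate mitochondrial code.
    """

    max_merge_mismatches: int = 5
    max_merge_gaps: int = 0
    max_expected_errors: float = 1.0
    index_length: int = 6
    max_homopolymer: int = 8
    allow_ambiguous: bool = False
    genetic_code: int = 5
    reading_frame: int = 0
    min_overlap: int = 16

    def __post_init__(self) -> None:
        if self.reading_frame not in (0, 1, 2):
            raise ValueError("reading_frame must be 0, 1 or 2")
        for name in ("max_merge_mismatches", "max_merge_gaps", "max_expected_errors",
                     "index_length", "max_homopolymer", "min_overlap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class UniqueSequence:
    """A dereplicated sequence with its read abundance and member read ids."""

    sequence: str
    abundance: int
    member_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.member_ids and self.abundance != len(self.member_ids):
            raise ValueError("abundance must equal the number of member ids")
        if self.abundance < 1:
            raise ValueError("abundance must be >= 1")


@dataclass(frozen=True)
class MergeResult:
    merged: str | None
    qualities: tuple[int, ...] | None
    overlap: int
    mismatches: int
    reason: str | None  # None on success

    @property
    def ok(self) -> bool:
        return self.reason is None


def merge_pair(pair: ReadPair, rules: FilterRules) -> MergeResult:
    """Merge a read pair by its best ungapped overlap.

    The reverse mate is reverse-complemented and slid along the forward mate;
    the overlap with the fewest mismatches wins, ties going to the longest
    overlap.  Consensus bases take the higher-quality call: agreeing bases get
    ``max(Qf, Qr)``, disagreeing bases get ``|Qf - Qr|``.
    """
    f, r = pair.fwd.upper(), reverse_complement(pair.rev.upper())
    rq = pair.rev_qual[::-1]
    fq = pair.fwd_qual
    if not f or not r:
        return MergeResult(None, None, 0, 0, "empty_mate")

    best: tuple[int, int] | None = None  # (mismatches, overlap)
    max_ov = min(len(f), len(r))
    for ov in range(rules.min_overlap, max_ov + 1):
        a, b = f[len(f) - ov:], r[:ov]
        mism = sum(1 for x, y in zip(a, b) if x != y)
        if best is None or mism < best[0] or (mism == best[0] and ov > best[1]):
            best = (mism, ov)
    if best is None:
        return MergeResult(None, None, 0, 0, "no_overlap")
    mism, ov = best
    if mism > rules.max_merge_mismatches:
        return MergeResult(None, None, ov, mism, "merge_mismatches")

    off = len(f) - ov
    cons, cons_q = [], []
    for i in range(ov):
        bf, br = f[off + i], r[i]
        qf, qr = fq[off + i], rq[i]
        if bf == br:
            cons.append(bf)
            cons_q.append(max(qf, qr))
        elif qf >= qr:
            cons.append(bf)
            cons_q.append(abs(qf - qr))
        else:
            cons.append(br)
            cons_q.append(abs(qf - qr))
    merged = f[:off] + "".join(cons) + r[ov:]
    quals = tuple(fq[:off]) + tuple(cons_q) + tuple(rq[ov:])
    return MergeResult(merged, quals, ov, mism, None)


def expected_errors(qualities) -> float:
    """Sum of Phred-implied per-base error probabilities, sum(10^(-Q/10))."""
    q = np.asarray(list(qualities), dtype=float)
    if q.size == 0:
        return 0.0
    return float(np.sum(10.0 ** (-q / 10.0)))


@dataclass(frozen=True)
class DemuxResult:
    sample_id: str | None
    trimmed: str | None
    reason: str | None

    @property
    def ok(self) -> bool:
        return self.reason is None


def demultiplex(
    merged: str,
    index_map: dict[str, str],
    primer_fwd: str,
    primer_rev: str,
    rules: FilterRules,
) -> DemuxResult:
    """Assign a merged read to a sample by its dual index; trim index+primers.

    Both termini must match index+primer exactly: index bases literally,
    primer bases under IUPAC degeneracy.  The forward-end index must equal the
    reverse-end index (tag-jump guard); conflicting indices are rejected as
    ``index_conflict``, unknown or mismatched ends as ``unknown_index``.
    """
    L = rules.index_length
    merged = merged.upper()
    if len(merged) < 2 * (L + max(len(primer_fwd), len(primer_rev))):
        return DemuxResult(None, None, "too_short")

    head = merged[: L + len(primer_fwd)]
    tail = reverse_complement(merged[-(L + len(primer_rev)):])

    def end_index(segment: str, primer: str) -> str | None:
        idx, rest = segment[:L], segment[L:]
        if not iupac_match(primer, rest):
            return None
        for sample, sample_idx in index_map.items():
            if idx == sample_idx.upper():
                return sample
        return None

    s_f = end_index(head, primer_fwd.upper())
    s_r = end_index(tail, primer_rev.upper())
    if s_f is None or s_r is None:
        return DemuxResult(None, None, "unknown_index")
    if s_f != s_r:
        return DemuxResult(None, None, "index_conflict")
    trimmed = merged[L + len(primer_fwd): len(merged) - (L + len(primer_rev))]
    return DemuxResult(s_f, trimmed, None)


def content_filters(sequence: str, rules: FilterRules) -> str | None:
    """Homopolymer and ambiguity screens; returns a rejection reason or None."""
    seq = sequence.upper()
    if not rules.allow_ambiguous and any(b not in "ACGT" for b in seq):
        return "ambiguous_base"
    run, prev = 0, ""
    for b in seq:
        run = run + 1 if b == prev else 1
        prev = b
        if run > rules.max_homopolymer:
            return "homopolymer"
    return None


def stop_codon_screen(
    sequence: str,
    genetic_code: int = 5,
    reading_frame: int = 0,
    expected_length: int | None = None,
) -> str | None:
    """Screen for in-frame stop codons under the given translation table.

    Returns None on pass, else a reason: ``stop_codon`` if any complete
    in-frame codon is a stop (TAA/TAG under table 5), ``too_short`` if no
    complete codon fits, or ``possible_frameshift`` when ``expected_length``
    is given and the sequence length differs from it by a non-multiple of 3
    (reference-alignment frameshift calling is out of scope; this length
    check is the only frameshift signal).
    """
    stops = frozenset(CodonTable.unambiguous_dna_by_id[genetic_code].stop_codons)
    seq = sequence.upper()[reading_frame:]
    if len(seq) < 3:
        return "too_short"
    if expected_length is not None and (len(sequence) - expected_length) % 3 != 0:
        return "possible_frameshift"
    for i in range(0, len(seq) - 2, 3):
        if seq[i:i + 3] in stops:
            return "stop_codon"
    return None


def dereplicate(sequences, ids=None) -> list[UniqueSequence]:
    """Group identical sequences; output ordered by descending abundance
    (ties broken lexicographically by sequence)."""
    groups: dict[str, list[str]] = collections.defaultdict(list)
    for i, seq in enumerate(sequences):
        rid = ids[i] if ids is not None else f"read{i}"
        groups[seq].append(rid)
    out = [
        UniqueSequence(seq, len(members), tuple(members))
        for seq, members in groups.items()
    ]
    out.sort(key=lambda u: (-u.abundance, u.sequence))
    return out


def _hamming(a: str, b: str) -> int | None:
    if len(a) != len(b):
        return None
    return sum(1 for x, y in zip(a, b) if x != y)


def precluster(uniques, max_diff: int = 3) -> list[UniqueSequence]:
    """Greedy abundance-ranked merging of near-identical uniques.

    A single pass from most to least abundant absorbs each sequence into the
    most abundant surviving earlier sequence within Hamming distance
    ``max_diff`` (equal lengths only; unequal lengths never merge).  Total
    abundance is conserved and the output is re-sorted by abundance.
    """
    ordered = sorted(uniques, key=lambda u: (-u.abundance, u.sequence))
    kept: list[dict] = []
    for u in ordered:
        absorber = None
        for k in kept:
            d = _hamming(k["sequence"], u.sequence)
            if d is not None and d <= max_diff:
                absorber = k
                break
        if absorber is None:
            kept.append({"sequence": u.sequence, "abundance": u.abundance,
                         "member_ids": list(u.member_ids)})
        else:
            absorber["abundance"] += u.abundance
            absorber["member_ids"].extend(u.member_ids)
    out = [UniqueSequence(k["sequence"], k["abundance"], tuple(k["member_ids"]))
           for k in kept]
    out.sort(key=lambda u: (-u.abundance, u.sequence))
    return out


def remove_singletons(uniques) -> list[UniqueSequence]:
    """Discard preclusters represented by a single read."""
    return [u for u in uniques if u.abundance >= 2]


# ---------------------------------------------------------------------------
# FASTQ / FASTA plumbing and the end-to-end QC driver
# ---------------------------------------------------------------------------

def read_fastq_pairs(fwd_path, rev_path) -> list[ReadPair]:
    """Read paired FASTQ (Phred offset 33) into ReadPair records."""
    from Bio import SeqIO

    fwd = list(SeqIO.parse(str(fwd_path), "fastq"))
    rev = list(SeqIO.parse(str(rev_path), "fastq"))
    if len(fwd) != len(rev):
        raise ValueError("paired FASTQ files have different read counts")
    pairs = []
    for fr, rr in zip(fwd, rev):
        pairs.append(
            ReadPair(
                fr.id,
                str(fr.seq),
                tuple(fr.letter_annotations["phred_quality"]),
                str(rr.seq),
                tuple(rr.letter_annotations["phred_quality"]),
            )
        )
    return pairs


def write_fasta_with_sizes(uniques, path) -> None:
    """Write uniques as FASTA with the usual ``;size=N`` abundance suffix."""
    with open(path, "w") as fh:
        for i, u in enumerate(uniques, start=1):
            fh.write(f">unique{i};size={u.abundance}\n{u.sequence}\n")


@dataclass
class QCResult:
    """Outcome of the full QC chain on a set of read pairs."""

    per_sample_uniques: dict[str, list[UniqueSequence]]
    ledger: collections.Counter = field(default_factory=collections.Counter)
    rejections: list[tuple[str, str, str]] = field(default_factory=list)  # id, stage, reason


def run_read_qc(
    pairs,
    index_map: dict[str, str],
    primer_fwd: str,
    primer_rev: str,
    rules: FilterRules | None = None,
    expected_length: int | None = None,
    precluster_max_diff: int | None = 3,
    drop_singletons: bool = True,
) -> QCResult:
    """Run merge -> EE filter -> demultiplex -> content filters -> stop-codon
    screen -> per-sample dereplication -> preclustering -> singleton removal.

    The ledger counts every input pair exactly once (passed or one rejection
    reason), so its values always sum to ``len(pairs)``.
    """
    if rules is None:
        rules = FilterRules()
    ledger: collections.Counter = collections.Counter()
    rejections: list[tuple[str, str, str]] = []
    per_sample: dict[str, list[tuple[str, str]]] = {s: [] for s in index_map}

    for pair in pairs:
        m = merge_pair(pair, rules)
        if not m.ok:
            ledger[m.reason] += 1
            rejections.append((pair.id, "merge", m.reason))
            continue
        if expected_errors(m.qualities) > rules.max_expected_errors:
            ledger["expected_errors"] += 1
            rejections.append((pair.id, "merge", "expected_errors"))
            continue
        d = demultiplex(m.merged, index_map, primer_fwd, primer_rev, rules)
        if not d.ok:
            ledger[d.reason] += 1
            rejections.append((pair.id, "demultiplex", d.reason))
            continue
        reason = content_filters(d.trimmed, rules)
        if reason is not None:
            ledger[reason] += 1
            rejections.append((pair.id, "content", reason))
            continue
        reason = stop_codon_screen(d.trimmed, rules.genetic_code, rules.reading_frame,
                                   expected_length)
        if reason is not None:
            ledger[reason] += 1
            rejections.append((pair.id, "stop_codon", reason))
            continue
        ledger["passed"] += 1
        per_sample[d.sample_id].append((pair.id, d.trimmed))

    uniques = {}
    for sample, items in per_sample.items():
        seqs = [s for _, s in items]
        ids = [i for i, _ in items]
        derep = dereplicate(seqs, ids)
        if precluster_max_diff is not None:
            derep = precluster(derep, precluster_max_diff)
        if drop_singletons:
            derep = remove_singletons(derep)
        uniques[sample] = derep
    return QCResult(uniques, ledger, rejections)
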