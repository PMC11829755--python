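"""Repetitive-locus quantification from multi-mapping reads.

A read aligning N times contributes 1/N to the coverage pile at every
position it aligns, conserving one unit of span per retained read.  Reads
are retained for a locus if (by default) every one of their alignments
lies fully within the locus interval.  Short insert fragments (mature
microRNA length) are recovered from paired reads by finding a
reverse-complementary prefix flanked by the sequencing adapter.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seq import hamming, revcomp
from .simulate import AlignmentRecord, AlignmentSet

#: Repetitive miR427 locus in the Xt9.1 assembly (0-based half-open).
DEFAULT_LOCUS = ("Chr03", 133185000, 133320000)

MATURE_MIR427 = "GAAAGTGCTTTCTGTTTTGGGCG"


def read_alignments_bed(path, locus=DEFAULT_LOCUS) -> AlignmentSet:
    """Read BED-like records: chrom, start, end, read_id, N (tab-separated)."""
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ValueError(f"line {ln}: expected 5 fields, got {len(fields)}")
            chrom, start, end, rid, n = fields[:5]
            records.append(AlignmentRecord(rid, chrom, int(start), int(end), int(n)))
    return AlignmentSet(records, locus)


def read_alignments_sam(path, locus=DEFAULT_LOCUS) -> AlignmentSet:
    """Read a SAM/BAM file, taking multiplicity from the NH tag (via pysam)."""
    import pysam

    records = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            n = aln.get_tag("NH") if aln.has_tag("NH") else 1
            records.append(
                AlignmentRecord(aln.query_name, aln.reference_name,
                                aln.reference_start, aln.reference_end, int(n))
            )
    return AlignmentSet(records, locus)


def _by_read(alignments: AlignmentSet) -> dict[str, list[AlignmentRecord]]:
    grouped: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for rec in alignments.records:
        grouped[rec.read_id].append(rec)
    return grouped


def _in_locus(rec: AlignmentRecord, locus) -> bool:
    chrom, ls, le = locus
    return rec.chrom == chrom and rec.start >= ls and rec.end <= le


def retain_locus_reads(
    alignments: AlignmentSet,
    locus=None,
    policy: str = "strict",
) -> set[str]:
    """Ids of reads retained for the locus; the retained count is the signal.

    ``policy="strict"`` (default) requires every alignment of the read to
    lie fully within the locus — counting reads that also map elsewhere
    would inflate the locus signal.  ``policy="any"`` retains a read if at
    least one alignment is inside.
    """
    if not alignments.records:
        raise ValueError("empty alignment set")
    locus = locus or alignments.locus
    if policy not in ("strict", "any"):
        raise ValueError(f"unknown retention policy {policy!r}")
    agg = all if policy == "strict" else any
    return {
        rid for rid, recs in _by_read(alignments).items()
        if agg(_in_locus(r, locus) for r in recs)
    }


def build_pile(alignments: AlignmentSet, retained: set[str], locus=None) -> np.ndarray:
    """1/N coverage pile over the locus for the retained reads.

    Total mass is exactly sum over reads of (1/N) x sum of alignment
    spans, asserted on every call.
    """
    locus = locus or alignments.locus
    chrom, ls, le = locus
    pile = np.zeros(le - ls)
    expected_mass = 0.0
    for rec in alignments.records:
        if rec.read_id not in retained:
            continue
        if not _in_locus(rec, locus):
            raise ValueError(f"alignment of retained read {rec.read_id!r} outside locus")
        w = 1.0 / rec.n_alignments
        pile[rec.start - ls:rec.end - ls] += w
        expected_mass += w * (rec.end - rec.start)
    assert abs(pile.sum() - expected_mass) < 1e-6 * max(1.0, expected_mass), \
        "pile mass not conserved"
    return pile


def write_bedgraph(pile: np.ndarray, locus, path) -> None:
    chrom, ls, _ = locus
    with open(path, "w") as fh:
        start = 0
        for i in range(1, len(pile) + 1):
            if i == len(pile) or pile[i] != pile[start]:
                if pile[start] != 0:
                    fh.write(f"{chrom}\t{ls + start}\t{ls + i}\t{pile[start]:g}\n")
                start = i


# ---------------------------------------------------------------- fragments

@dataclass
class Fragment:
    pair_id: str
    length: int
    sequence: str


@dataclass
class FragmentSet:
    fragments: list[Fragment]
    unrecovered: list[str] = field(default_factory=list)


def infer_fragments(
    read_pairs: Sequence[tuple[str, str, str]],
    adapter_seq: str,
    read_len: int | None = None,
    max_mismatch: int = 0,
) -> FragmentSet:
    """Recover short insert fragments from adapter read-through pairs.

    For each candidate fragment length f = 1..read_len-1 (smallest first),
    a pair is accepted when (i) R1[:f] equals the reverse complement of
    R2[:f] with <= max_mismatch mismatches, and (ii) the remainder of R1
    matches the adapter prefix with <= max_mismatch mismatches over the
    available overlap.  The fragment sequence is R1[:f].
    """
    if len(adapter_seq) < 5:
        raise ValueError("adapter shorter than 5 nt")

    def _mismatch_le(a: str, b: str, k: int) -> bool:
        if k == 0:
            return a == b
        m = 0
        for x, y in zip(a, b):
            if x != y:
                m += 1
                if m > k:
                    return False
        return True

    fragments, unrecovered = [], []
    for pid, r1, r2 in read_pairs:
        if len(r1) != len(r2):
            raise ValueError(f"pair {pid!r}: R1/R2 length mismatch")
        n = read_len or len(r1)
        found = None
        for f in range(1, n):
            if not _mismatch_le(r1[:f], revcomp(r2[:f]), max_mismatch):
                continue
            tail = r1[f:]
            overlap = min(len(adapter_seq), len(tail))
            if overlap > 0 and not _mismatch_le(tail[:overlap], adapter_seq[:overlap], max_mismatch):
                continue
            found = f
            break
        if found is None:
            unrecovered.append(pid)
        else:
            fragments.append(Fragment(pid, found, r1[:found]))
    return FragmentSet(fragments, unrecovered)


def count_mature_instances(fragments: FragmentSet | Iterable[Fragment], query_seq: str) -> dict[int, int]:
    """Length histogram of fragments carrying the mature-sequence query.

    A fragment of length >= the query counts when it contains the query
    as a substring; a shorter fragment counts when it is itself a
    substring of the query (how a 22-bp fragment can still be an instance
    of a 23-nt mature sequence).
    """
    if not query_seq:
        raise ValueError("empty query")
    if isinstance(fragments, FragmentSet):
        fragments = fragments.fragments
    hist: dict[int, int] = {}
    for frag in fragments:
        seq = frag.sequence
        hit = (query_seq in seq) if len(seq) >= len(query_seq) else (seq in query_seq)
        if hit:
            hist[frag.length] = hist.get(frag.length, 0) + 1
    return dict(sorted(hist.items()))
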