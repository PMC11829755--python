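"""3'-UTR element-motif and microRNA-seed enrichment.

Seeds are represented in transcriptome space: the reverse complement of
the microRNA subsequence with U exchanged for T, so a perfect seed match
is a literal substring of the (transcript-sense, DNA-space) UTR.  Seed
classes default to the canonical 7-mer (miRNA nt 2-8), offset 6-mer
(nt 3-8) and extended 8-mer (nt 2-9).  Each seed also carries its minimum
Hamming distance to the miR427 extended seed region AAAGCACTTTC.

Per-cluster enrichment is a Fisher right-tail test of "gene has >= N
copies" against "gene is in the cluster"; element motifs (EDEN, ARE,
YTHDF2) are tested at N = 1 only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from Bio import SeqIO

from ._seq import hamming, iupac_regex, revcomp, rna_to_dna

#: Extended miR427 seed region: reverse complement of the first 11 nt of
#: mature miR427 (GAAAGUGCUUUcuguuuugggcg).
MIR427_EXTENDED_SEED = "AAAGCACTTTC"

ELEMENT_MOTIFS = {
    # transcript DNA space (U -> T)
    "EDEN": rna_to_dna("UAUAUAUGUGUGUCUAUCGUCACUUGUAUGUCAAAUAUU"),
    "ARE": "ATTA",
    "YTHDF2": "RRACH",
}

DEFAULT_SEED_CLASSES = {
    # 1-based inclusive positions within the mature miRNA
    "canonical_7mer": (2, 8),
    "offset_6mer": (3, 8),
    "extended_8mer": (2, 9),
}


@dataclass(frozen=True)
class SeedEntry:
    mirna_id: str
    seed: str  # transcriptome space
    seed_class: str
    mismatch_to_mir427: int


@dataclass
class SeedCatalog:
    entries: list[SeedEntry]

    def __iter__(self):
        return iter(self.entries)

    def seeds(self) -> list[str]:
        return sorted({e.seed for e in self.entries})


def mismatch_class(seed: str, reference: str = MIR427_EXTENDED_SEED) -> int:
    """Minimum Hamming distance of ``seed`` over all offsets within ``reference``."""
    if len(seed) > len(reference):
        raise ValueError(f"seed longer than the {len(reference)} nt reference")
    return min(
        hamming(seed, reference[off:off + len(seed)])
        for off in range(len(reference) - len(seed) + 1)
    )


def build_seed_catalog(
    mirnas: Mapping[str, str] | str,
    seed_classes: Mapping[str, tuple[int, int]] | None = None,
) -> SeedCatalog:
    """Seed catalog from mature miRNA sequences (dict or FASTA path).

    For each (miRNA, class) the seed is the reverse complement, U -> T, of
    the class's subsequence (1-based inclusive positions in the mature
    5'->3' sequence).
    """
    if isinstance(mirnas, str):
        mirnas = {rec.id: str(rec.seq) for rec in SeqIO.parse(mirnas, "fasta")}
    seed_classes = seed_classes or DEFAULT_SEED_CLASSES
    entries = []
    for mid, seq in mirnas.items():
        dna = rna_to_dna(seq)
        for cls, (lo, hi) in seed_classes.items():
            if hi > len(dna):
                raise ValueError(f"{mid}: sequence shorter than position {hi} for class {cls}")
            sub = dna[lo - 1:hi]
            seed = revcomp(sub)
            entries.append(SeedEntry(mid, seed, cls, mismatch_class(seed)))
    return SeedCatalog(entries)


def count_matches(sequence: str, pattern: str) -> int:
    """Number of (overlapping) start positions of an IUPAC pattern.

    An ``N`` in the sequence never matches.
    """
    return len(iupac_regex(pattern).findall(sequence.upper()))


def gene_level_counts(
    utrs: Mapping[str, str],
    pattern: str,
    aggregation: str = "max_over_isoforms",
) -> dict[str, int]:
    """Per-gene pattern counts from per-isoform UTRs (headers ``gene|isoform``)."""
    if aggregation not in ("max_over_isoforms", "sum_over_isoforms"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    per_gene: dict[str, list[int]] = {}
    for header, seq in utrs.items():
        gene = header.split("|", 1)[0]
        per_gene.setdefault(gene, []).append(count_matches(seq, pattern))
    agg = max if aggregation == "max_over_isoforms" else sum
    return {g: int(agg(cs)) for g, cs in per_gene.items()}


def fisher_right_tail(a: int, b: int, c: int, d: int) -> float:
    """Right-tail Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    return float(fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def enrichment_matrix(
    cluster_map: Mapping[str, str | None],
    per_gene_counts: Mapping[str, Mapping[str, int]],
    n_max: int = 6,
    element_patterns: Iterable[str] = (),
    seed_meta: Mapping[str, dict] | None = None,
) -> pd.DataFrame:
    """Fisher enrichment of >= N pattern copies per cluster.

    ``cluster_map`` assigns every filtered gene to a cluster or to the
    background (None).  ``per_gene_counts`` maps pattern -> {gene: count}.
    Patterns listed in ``element_patterns`` are tested at N = 1 only;
    every other pattern at N = 1..n_max.  Returns a long-format table
    (pattern, cluster, N, a, b, c, d, p, neglog10p).
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    clusters = sorted({c for c in cluster_map.values() if c is not None})
    genes = list(cluster_map)
    element_patterns = set(element_patterns)
    rows = []
    for pattern, counts in per_gene_counts.items():
        missing = [g for g in genes if g not in counts]
        if missing:
            raise KeyError(f"genes in cluster_map missing from counts: {missing[:5]}")
        cvec = np.array([counts[g] for g in genes])
        ns = (1,) if pattern in element_patterns else tuple(range(1, n_max + 1))
        for cluster in clusters:
            in_c = np.array([cluster_map[g] == cluster for g in genes])
            for n in ns:
                has = cvec >= n
                a = int(np.sum(in_c & has))
                b = int(np.sum(in_c & ~has))
                c = int(np.sum(~in_c & has))
                d = int(np.sum(~in_c & ~has))
                p = fisher_right_tail(a, b, c, d)
                row = {
                    "pattern": pattern, "cluster": cluster, "N": n,
                    "a": a, "b": b, "c": c, "d": d,
                    "p": p, "neglog10p": -math.log10(p) if p > 0 else math.inf,
                }
                if seed_meta and pattern in seed_meta:
                    row.update(seed_meta[pattern])
                rows.append(row)
    return pd.DataFrame(rows)
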