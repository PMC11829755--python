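"""Promoter PWM scanning and threshold-optimized cluster enrichment.

PWMs (JASPAR-style count matrices) are converted to probability matrices
with a background-distributed pseudocount and scored as log2 likelihood
ratios against genomic base frequencies.  Each gene's score is the
maximum over all 500-bp promoter windows (both strands by default); the
per-motif score threshold is the value > 5 that maximizes the Fisher
association between having an above-threshold motif and being in any
cluster, after which per-cluster enrichment is reported at that threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from ._seq import revcomp
from .utr import fisher_right_tail

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class PWM:
    name: str
    matrix: np.ndarray  # (4, width) probabilities, columns sum to 1
    background: np.ndarray  # length-4 genome base frequencies

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 1:
            raise ValueError("matrix must be 4 x width with width >= 1")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if not math.isclose(self.background.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))

    @property
    def max_score(self) -> float:
        with np.errstate(divide="ignore"):
            lr = np.log2(self.matrix / self.background[:, None])
        return float(lr.max(axis=0).sum())


def pwm_from_counts(
    count_matrix,
    pseudocount: float = 0.8,
    background=(0.25, 0.25, 0.25, 0.25),
    name: str = "pwm",
) -> PWM:
    """Probability PWM from a 4 x width count matrix.

    Per column: p = (count + pseudocount * background) / (total + pseudocount),
    the common JASPAR practice of distributing the pseudocount by background.
    """
    counts = np.asarray(count_matrix, dtype=float)
    bg = np.asarray(background, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValueError("count matrix must be 4 x width (rows A, C, G, T)")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=0)
    if pseudocount == 0 and np.any(totals == 0):
        raise ValueError("zero-total column with zero pseudocount")
    probs = (counts + pseudocount * bg[:, None]) / (totals + pseudocount)
    return PWM(name, probs, bg / bg.sum())


def read_jaspar(path, pseudocount: float = 0.8, background=(0.25,) * 4) -> dict[str, PWM]:
    """Read JASPAR-format count matrices into PWMs (via Bio.motifs)."""
    pwms = {}
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in BASES], dtype=float)
            name = m.matrix_id or m.name
            pwms[name] = pwm_from_counts(counts, pseudocount, background, name=name)
    return pwms


def score_site(pwm: PWM, site: str) -> float:
    """Log2 likelihood-ratio score of one width-length site.

    An ``N`` base contributes 0 (scores as background).
    """
    if len(site) != pwm.width:
        raise ValueError(f"site length {len(site)} != PWM width {pwm.width}")
    with np.errstate(divide="ignore"):
        lr = np.log2(pwm.matrix / pwm.background[:, None])
    score = 0.0
    for j, base in enumerate(site.upper()):
        if base == "N":
            continue
        try:
            score += lr[_BASE_INDEX[base], j]
        except KeyError:
            raise ValueError(f"unexpected base {base!r}") from None
    return float(score)


def _scan_max(pwm: PWM, seq: str) -> float:
    """Max window score along one strand (vectorized over windows)."""
    w = pwm.width
    if len(seq) < w:
        raise ValueError(f"sequence shorter than PWM width {w}")
    with np.errstate(divide="ignore"):
        lr = np.log2(pwm.matrix / pwm.background[:, None])
    lr = np.vstack([lr, np.zeros(w)])  # row 4: N contributes 0
    idx = np.array([_BASE_INDEX.get(b, 4) for b in seq.upper()])
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    return float(lr[windows, np.arange(w)].sum(axis=1).max())


def gene_max_score(pwm: PWM, promoters: Iterable[str], strands: str = "both") -> float:
    """Maximal motif score over all promoters (and strands) of a gene."""
    if strands not in ("both", "forward"):
        raise ValueError("strands must be 'both' or 'forward'")
    best = -math.inf
    for seq in promoters:
        best = max(best, _scan_max(pwm, seq))
        if strands == "both":
            best = max(best, _scan_max(pwm, revcomp(seq)))
    if best == -math.inf:
        raise ValueError("gene has no promoter sequence")
    return best


@dataclass
class MotifThreshold:
    motif: str
    threshold: float
    max_score_observed: float
    p_at_threshold: float


def optimize_threshold(
    gene_scores: Mapping[str, float],
    in_any_cluster: Mapping[str, bool],
    min_threshold: float = 5.0,
    motif: str = "pwm",
) -> MotifThreshold:
    """Score threshold > ``min_threshold`` maximizing cluster association.

    Candidates are the distinct observed scores above ``min_threshold``;
    for each, the Fisher right-tail p of (score >= threshold) x (in any
    cluster) is evaluated and the minimizing threshold returned, ties
    broken toward the lower threshold.
    """
    genes = list(gene_scores)
    scores = np.array([gene_scores[g] for g in genes])
    member = np.array([bool(in_any_cluster[g]) for g in genes])
    candidates = sorted({s for s in scores if s > min_threshold})
    if not candidates:
        raise ValueError(f"no score exceeds the minimum threshold {min_threshold}")
    best = None
    for t in candidates:
        has = scores >= t
        p = fisher_right_tail(
            int(np.sum(member & has)), int(np.sum(member & ~has)),
            int(np.sum(~member & has)), int(np.sum(~member & ~has)),
        )
        if best is None or p < best[1] - 1e-15:
            best = (t, p)
    return MotifThreshold(motif, float(best[0]), float(scores.max()), float(best[1]))


def cluster_enrichment_at_threshold(
    gene_scores: Mapping[str, Mapping[str, float]],
    thresholds: Mapping[str, MotifThreshold | float],
    cluster_map: Mapping[str, str | None],
) -> pd.DataFrame:
    """Per-(motif, cluster) Fisher enrichment of above-threshold genes.

    ``gene_scores`` maps motif -> {gene: max score}; ``cluster_map``
    assigns genes to clusters or the background (None).
    """
    clusters = sorted({c for c in cluster_map.values() if c is not None})
    genes = list(cluster_map)
    if any(not any(cluster_map[g] == c for g in genes) for c in clusters):
        raise ValueError("cluster with zero genes")
    rows = []
    for motif, scores in gene_scores.items():
        t = thresholds[motif]
        t = t.threshold if isinstance(t, MotifThreshold) else float(t)
        has = np.array([scores[g] >= t for g in genes])
        for cluster in clusters:
            in_c = np.array([cluster_map[g] == cluster for g in genes])
            a = int(np.sum(in_c & has))
            b = int(np.sum(in_c & ~has))
            c = int(np.sum(~in_c & has))
            d = int(np.sum(~in_c & ~has))
            p = fisher_right_tail(a, b, c, d)
            rows.append({
                "motif": motif, "cluster": cluster, "threshold": t,
                "a": a, "b": b, "c": c, "d": d,
                "p": p, "neglog10p": -math.log10(p) if p > 0 else math.inf,
            })
    return pd.DataFrame(rows)
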