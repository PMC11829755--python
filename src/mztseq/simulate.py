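"""Synthetic data with the statistical structure the pipeline assumes.

Generates every input the analysis consumes: two-condition (UIC vs MO)
TPM time courses for polyA+ and ribozero library types with planted
trajectory classes, 3'-UTR and promoter sequences with planted seed/motif
copies, multi-mapping locus alignments, and adapter read-through paired
reads — each alongside an exact machine-readable truth record.

The time grid emulates 30-minute sampling across a developmental window
(20 points at 0.5 h spacing by default).  Expression noise is
multiplicative lognormal with a configurable coefficient of variation:
simple, strictly positive, and monotone under the log-family VST.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from ._seq import revcomp, iupac_regex
from .expression import CONDITIONS, ExpressionDataset

BASES = "ACGT"

#: Standard Illumina TruSeq adapters (read 1 / read 2).
TRUSEQ_R1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
TRUSEQ_R2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT"

TRAJECTORY_FAMILIES = ("maternal_decay", "zygotic_sigmoid", "constant")


@dataclass(frozen=True)
class ClusterSpec:
    """One planted trajectory class.

    effect > 1 on a maternal_decay family blocks/limits clearance from the
    divergence onset (MO held near its onset level, capped at effect x UIC),
    so MO >= UIC at every t >= onset.  effect != 1 on zygotic_sigmoid or
    constant scales the response from the onset (e.g. effect < 1 gives a
    'decreased' gene).  effect == 1 is a null class.
    """

    label: str
    n_genes: int
    family: str
    onset: float  # hours; divergence onset between UIC and MO
    effect: float = 1.0


@dataclass
class SimulationConfig:
    n_genes: int = 600
    n_timepoints: int = 20
    t_start: float = 0.0
    dt: float = 0.5
    cluster_spec: list[ClusterSpec] = field(default_factory=list)
    noise_cv: float = 0.1
    seed: int = 0
    library_types: tuple[str, ...] = ("polyA+", "ribozero")
    high_tpm: float = 100.0
    low_tpm: float = 2.0
    sigmoid_width: float = 0.5
    onset_to_midpoint: float = 1.0  # hours from divergence onset to sigmoid midpoint

    @property
    def timepoints(self) -> np.ndarray:
        return self.t_start + self.dt * np.arange(self.n_timepoints)

    def validate(self) -> None:
        if self.n_timepoints <= 0:
            raise ValueError("n_timepoints must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if sum(cs.n_genes for cs in self.cluster_spec) > self.n_genes:
            raise ValueError("cluster_spec gene counts exceed n_genes")
        for cs in self.cluster_spec:
            if cs.family not in TRAJECTORY_FAMILIES:
                raise ValueError(f"unknown trajectory family {cs.family!r}")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


@dataclass
class PlantedTruth:
    """Ground-truth record; every planted item is recoverable without
    re-deriving it from emitted sequence or tables."""

    cluster_labels: dict[str, str | None] = field(default_factory=dict)
    gene_params: dict[str, dict] = field(default_factory=dict)
    utr_copies: dict[str, dict] = field(default_factory=dict)
    promoter_sites: dict[str, int | None] = field(default_factory=dict)
    in_locus_reads: list[str] = field(default_factory=list)
    read_multiplicity: dict[str, int] = field(default_factory=dict)
    fragments: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _uic_trajectory(family: str, t: np.ndarray, midpoint: float,
                    hi: float, lo: float, width: float) -> np.ndarray:
    if family == "maternal_decay":
        return lo + (hi - lo) * _sigmoid(-(t - midpoint) / width)
    if family == "zygotic_sigmoid":
        return lo + (hi - lo) * _sigmoid((t - midpoint) / width)
    if family == "constant":
        return np.full_like(t, hi)
    raise ValueError(f"unknown trajectory family {family!r}")


def _mo_trajectory(family: str, uic: np.ndarray, t: np.ndarray,
                   onset: float, effect: float, lo: float) -> np.ndarray:
    mo = uic.copy()
    if effect == 1.0:
        return mo
    mask = t >= onset
    if family == "maternal_decay" and effect > 1.0:
        hold = float(np.interp(onset, t, uic))  # level at clearance block
        mo[mask] = np.maximum(uic[mask], np.minimum(hold, effect * uic[mask]))
    elif family == "constant":
        mo[mask] = effect * uic[mask]
    else:  # scaled response around the floor
        mo[mask] = lo + effect * (uic[mask] - lo)
    return mo


def simulate_timecourse(config: SimulationConfig):
    """Simulate TPM matrices per library type plus the planted truth.

    Planted cluster genes come first (in cluster_spec order); remaining
    genes are null, with a trajectory family, midpoint and amplitude drawn
    per gene but shared exactly between UIC and MO.  Noise is independent
    multiplicative lognormal (unit mean) per sample and library type.
    Deterministic given the config and seed.
    """
    config.validate()
    t = config.timepoints
    rng_traj = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))

    gene_ids, labels, means = [], {}, []
    params: dict[str, dict] = {}
    gi = 0
    for cs in config.cluster_spec:
        for _ in range(cs.n_genes):
            g = f"g{gi:05d}"
            midpoint = cs.onset + config.onset_to_midpoint
            uic = _uic_trajectory(cs.family, t, midpoint, config.high_tpm,
                                  config.low_tpm, config.sigmoid_width)
            mo = _mo_trajectory(cs.family, uic, t, cs.onset, cs.effect, config.low_tpm)
            gene_ids.append(g)
            labels[g] = cs.label
            params[g] = {"family": cs.family, "onset": cs.onset, "effect": cs.effect}
            means.append(np.stack([uic, mo], axis=1))
            gi += 1
    n_null = config.n_genes - gi
    t_span = (t[0], t[-1])
    for j in range(n_null):
        g = f"g{gi:05d}"
        family = TRAJECTORY_FAMILIES[j % len(TRAJECTORY_FAMILIES)]
        midpoint = float(rng_traj.uniform(*t_span))
        amp = float(config.high_tpm * rng_traj.lognormal(0.0, 0.5))
        uic = _uic_trajectory(family, t, midpoint, amp, config.low_tpm, config.sigmoid_width)
        gene_ids.append(g)
        labels[g] = None
        params[g] = {"family": family, "onset": None, "effect": 1.0}
        means.append(np.stack([uic, uic], axis=1))
        gi += 1
    mean_arr = np.stack(means) if means else np.zeros((0, t.size, 2))

    datasets = {}
    for li, lib in enumerate(config.library_types):
        rng_noise = np.random.default_rng(np.random.SeedSequence([config.seed, 1 + li]))
        if config.noise_cv > 0:
            sigma = math.sqrt(math.log1p(config.noise_cv**2))
            factors = rng_noise.lognormal(-0.5 * sigma**2, sigma, size=mean_arr.shape)
        else:
            factors = 1.0
        datasets[lib] = ExpressionDataset(list(gene_ids), t.copy(), mean_arr * factors, lib)
    truth = PlantedTruth(cluster_labels=labels, gene_params=params)
    return datasets, truth


# ---------------------------------------------------------------- sequences

def _random_seq(rng: np.random.Generator, length: int, base_freqs=None) -> str:
    p = None if base_freqs is None else np.asarray(base_freqs, dtype=float)
    if p is not None:
        p = p / p.sum()
    return "".join(rng.choice(list(BASES), size=length, p=p))


def _count_exact(seq: str, pattern: str) -> int:
    return len(iupac_regex(pattern).findall(seq))


def simulate_utrs(
    gene_ids: Sequence[str],
    copy_spec: Mapping[str, tuple[str, int]],
    utr_length: int = 200,
    rng_seed: int = 0,
    base_freqs=None,
    max_tries: int = 2000,
):
    """3'-UTR sequences with exact planted seed copy numbers.

    ``copy_spec`` maps gene ids to (seed string, copies); genes not listed
    get zero copies.  Background sequence is i.i.d. and rejection-sampled
    so that each emitted UTR contains exactly its planted number of
    (non-overlapping) copies of every seed appearing in the spec — chance
    copies are rejected, making planted counts exact.  Headers are
    ``gene|utr1``.
    """
    rng = np.random.default_rng(rng_seed)
    seeds_in_play = sorted({s for s, _ in copy_spec.values()})
    seqs: dict[str, str] = {}
    truth = PlantedTruth()
    for gene in gene_ids:
        seed, copies = copy_spec.get(gene, (None, 0))
        if seed is not None and copies * len(seed) > utr_length:
            raise ValueError(f"UTR length {utr_length} too short for {copies} copies of {seed!r}")
        for _ in range(max_tries):
            seq = _random_seq(rng, utr_length, base_freqs)
            if copies > 0:
                # place non-overlapping copies at random starts
                starts: list[int] = []
                ok = True
                for _c in range(copies):
                    for _try in range(200):
                        s = int(rng.integers(0, utr_length - len(seed) + 1))
                        if all(s + len(seed) <= o or s >= o + len(seed) for o in starts):
                            starts.append(s)
                            break
                    else:
                        ok = False
                        break
                if not ok:
                    continue
                chars = list(seq)
                for s in starts:
                    chars[s:s + len(seed)] = seed
                seq = "".join(chars)
            wanted = {s: (copies if s == seed else 0) for s in seeds_in_play}
            if all(_count_exact(seq, s) == c for s, c in wanted.items()):
                break
        else:
            raise RuntimeError(f"could not place copies for gene {gene!r} after {max_tries} tries")
        seqs[f"{gene}|utr1"] = seq
        truth.utr_copies[gene] = {"seed": seed, "copies": copies}
    return seqs, truth


def pwm_consensus(matrix: np.ndarray) -> str:
    """Consensus sequence of a PWM probability (or count) matrix (4 x width)."""
    return "".join(BASES[i] for i in np.asarray(matrix).argmax(axis=0))


def simulate_promoters(
    gene_ids: Sequence[str],
    pwm_matrix: np.ndarray,
    planted_fraction: float,
    rng_seed: int = 0,
    length: int = 500,
    base_freqs=None,
    max_tries: int = 2000,
):
    """500-bp promoters, a fraction of which carry the PWM consensus.

    Planted promoters contain the consensus site exactly once (forward
    strand) at a recorded offset; all other sequence is rejection-sampled
    to contain no consensus occurrence on either strand.
    """
    if not 0.0 <= planted_fraction <= 1.0:
        raise ValueError("planted_fraction outside [0, 1]")
    consensus = pwm_consensus(pwm_matrix)
    if length < len(consensus):
        raise ValueError("promoter shorter than the PWM width")
    rng = np.random.default_rng(rng_seed)
    n_planted = int(round(planted_fraction * len(gene_ids)))
    planted = set(rng.choice(len(gene_ids), size=n_planted, replace=False).tolist())
    rc = revcomp(consensus)

    seqs: dict[str, str] = {}
    truth = PlantedTruth()
    for i, gene in enumerate(gene_ids):
        want = 1 if i in planted else 0
        for _ in range(max_tries):
            seq = _random_seq(rng, length, base_freqs)
            offset = None
            if want:
                offset = int(rng.integers(0, length - len(consensus) + 1))
                seq = seq[:offset] + consensus + seq[offset + len(consensus):]
            if _count_exact(seq, consensus) == want and _count_exact(seq, rc) == (
                1 if want and rc == consensus else 0
            ):
                break
        else:
            raise RuntimeError(f"rejection sampling failed for promoter {gene!r}")
        seqs[f"{gene}|prom1"] = seq
        truth.promoter_sites[gene] = offset
    return seqs, truth


# ---------------------------------------------------------------- reads

@dataclass
class AlignmentRecord:
    read_id: str
    chrom: str
    start: int  # 0-based, half-open
    end: int
    n_alignments: int


@dataclass
class AlignmentSet:
    records: list[AlignmentRecord]
    locus: tuple[str, int, int]

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.read_id}\t{r.n_alignments}\n")


def simulate_locus_alignments(
    n_reads: int,
    multiplicity_dist: Mapping[int, float],
    locus_interval: tuple[str, int, int] = ("Chr03", 133185000, 133320000),
    read_span: int = 150,
    rng_seed: int = 0,
    in_locus_fraction: float = 1.0,
):
    """Multi-mapping alignment records for a repetitive locus.

    Each read draws a multiplicity N from ``multiplicity_dist`` and, if
    in-locus, places all N alignments uniformly inside the locus interval;
    out-of-locus reads place all alignments on a decoy chromosome.  The
    truth records the in-locus read ids and every read's N.
    """
    chrom, ls, le = locus_interval
    if le - ls < read_span:
        raise ValueError("locus shorter than read_span")
    rng = np.random.default_rng(rng_seed)
    ns = sorted(multiplicity_dist)
    if min(ns) < 1:
        raise ValueError("multiplicities must be >= 1")
    probs = np.array([multiplicity_dist[n] for n in ns], dtype=float)
    probs = probs / probs.sum()

    n_in = int(round(in_locus_fraction * n_reads))
    in_flags = np.zeros(n_reads, dtype=bool)
    in_flags[rng.permutation(n_reads)[:n_in]] = True

    records: list[AlignmentRecord] = []
    truth = PlantedTruth()
    for i in range(n_reads):
        rid = f"r{i:06d}"
        n_aln = int(rng.choice(ns, p=probs))
        truth.read_multiplicity[rid] = n_aln
        if in_flags[i]:
            truth.in_locus_reads.append(rid)
            starts = rng.integers(ls, le - read_span + 1, size=n_aln)
            for s in starts:
                records.append(AlignmentRecord(rid, chrom, int(s), int(s) + read_span, n_aln))
        else:
            starts = rng.integers(0, 10_000_000, size=n_aln)
            for s in starts:
                records.append(AlignmentRecord(rid, "ChrDecoy", int(s), int(s) + read_span, n_aln))
    return AlignmentSet(records, locus_interval), truth


def simulate_read_pairs(
    fragments: Mapping[str, str] | Sequence[str],
    adapter_r1: str = TRUSEQ_R1,
    adapter_r2: str = TRUSEQ_R2,
    read_len: int = 150,
    rng_seed: int = 0,
):
    """Paired reads with adapter read-through for short insert fragments.

    For a fragment shorter than the read length, R1 is the fragment
    followed by the read-1 adapter (random bases pad to read_len), and R2
    is the reverse complement of the fragment followed by the read-2
    adapter.  Fragments of length >= read_len truncate with no adapter and
    are marked unrecoverable in the truth.
    """
    if isinstance(fragments, Mapping):
        items = list(fragments.items())
    else:
        items = [(f"p{i:05d}", f) for i, f in enumerate(fragments)]
    rng = np.random.default_rng(rng_seed)
    pairs: list[tuple[str, str, str]] = []
    truth = PlantedTruth()
    for pid, frag in items:
        if len(frag) < read_len:
            pad1 = _random_seq(rng, max(0, read_len - len(frag) - len(adapter_r1)))
            pad2 = _random_seq(rng, max(0, read_len - len(frag) - len(adapter_r2)))
            r1 = (frag + adapter_r1 + pad1)[:read_len]
            r2 = (revcomp(frag) + adapter_r2 + pad2)[:read_len]
            recoverable = True
        else:
            r1 = frag[:read_len]
            r2 = revcomp(frag)[:read_len]
            recoverable = False
        pairs.append((pid, r1, r2))
        truth.fragments[pid] = {
            "length": len(frag), "sequence": frag, "recoverable": recoverable,
        }
    return pairs, truth


def write_fasta(seqs: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def write_fastq_pairs(pairs, path_r1, path_r2) -> None:
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for pid, r1, r2 in pairs:
            f1.write(f"@{pid}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{pid}/2\n{r2}\n+\n{'I' * len(r2)}\n")
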