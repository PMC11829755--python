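"""Expression-table intake: TSV reading, abundance correction, expressed-gene filter.

The container holds a genes x timepoints x {UIC, MO} TPM array for one
library preparation (polyA+ or ribozero).  The expressed-gene filter keeps
genes showing a run of ``run_len`` consecutive samples with TPM strictly
above ``min_tpm`` in *every* supplied library type, on uncorrected TPM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("UIC", "MO")


@dataclass
class ExpressionDataset:
    """TPM values for one library type over an ordered shared time grid.

    ``tpm`` has shape (n_genes, n_timepoints, 2) with the last axis ordered
    as :data:`CONDITIONS`.  ``gene_max`` (the per-gene m_i) is the maximum
    abundance over both conditions and all timepoints.
    """

    gene_ids: list[str]
    timepoints: np.ndarray
    tpm: np.ndarray
    library_type: str = "polyA+"

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.tpm = np.asarray(self.tpm, dtype=float)
        if self.tpm.shape != (len(self.gene_ids), self.timepoints.size, 2):
            raise ValueError(
                f"tpm shape {self.tpm.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {self.timepoints.size} timepoints x 2 conditions"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = {g for g in self.gene_ids if self.gene_ids.count(g) > 1}
            raise ValueError(f"duplicate gene_id(s): {sorted(dupes)[:5]}")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(self.tpm < 0):
            g, t, c = map(int, np.argwhere(self.tpm < 0)[0])
            raise ValueError(
                f"negative TPM at gene {self.gene_ids[g]!r}, "
                f"t={self.timepoints[t]:g}, condition {CONDITIONS[c]}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def gene_max(self) -> np.ndarray:
        """m_i: per-gene maximum over all samples (both conditions)."""
        return self.tpm.max(axis=(1, 2))

    def series(self, gene_id: str, condition: str) -> np.ndarray:
        return self.tpm[self.gene_ids.index(gene_id), :, CONDITIONS.index(condition)]

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for ci, cond in enumerate(CONDITIONS):
            for ti, t in enumerate(self.timepoints):
                cols[f"{cond}_{t:g}"] = self.tpm[:, ti, ci]
        return pd.DataFrame(cols, index=pd.Index(self.gene_ids, name="gene_id"))

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def read_tpm_table(path, library_type: str = "polyA+") -> ExpressionDataset:
    """Read a TSV expression table (gene_id column, then ``{condition}_{t}`` columns)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id":
        raise ValueError(f"first column must be 'gene_id', got {df.columns[0]!r}")
    df = df.set_index("gene_id")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene_id(s): {dupes[:5]}")

    parsed: dict[str, list[tuple[float, str]]] = {c: [] for c in CONDITIONS}
    for col in df.columns:
        cond, _, t = col.partition("_")
        if cond not in CONDITIONS or not t:
            raise ValueError(f"column {col!r}: expected '<condition>_<time>' with condition in {CONDITIONS}")
        parsed[cond].append((float(t), col))
    for cond in CONDITIONS:
        if not parsed[cond]:
            raise ValueError(f"missing condition {cond!r} in header")
        parsed[cond].sort()
    times_u = [t for t, _ in parsed["UIC"]]
    times_m = [t for t, _ in parsed["MO"]]
    if times_u != times_m:
        raise ValueError("UIC and MO must share the identical time grid")

    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.argmax((bad | df[col].isna()).to_numpy()))
            raise ValueError(f"non-numeric cell at row {row + 2} (gene {df.index[row]!r}), column {col!r}")
    tpm = np.stack(
        [df[[c for _, c in parsed[cond]]].to_numpy(dtype=float) for cond in CONDITIONS],
        axis=2,
    )
    return ExpressionDataset(list(df.index), np.array(times_u), tpm, library_type)


def correct_abundance(
    dataset: ExpressionDataset, correction: Mapping[str, float] | None
) -> ExpressionDataset:
    """Apply a per-gene multiplicative abundance correction (identity if None).

    The gene maxima m_i are implicitly recomputed since they are derived
    from the corrected values.
    """
    if correction is None:
        return ExpressionDataset(
            list(dataset.gene_ids), dataset.timepoints.copy(), dataset.tpm.copy(), dataset.library_type
        )
    missing = [g for g in dataset.gene_ids if g not in correction]
    if missing:
        raise KeyError(f"correction table missing gene(s): {missing[:5]}")
    factors = np.array([correction[g] for g in dataset.gene_ids], dtype=float)
    return ExpressionDataset(
        list(dataset.gene_ids),
        dataset.timepoints.copy(),
        dataset.tpm * factors[:, None, None],
        dataset.library_type,
    )


def _max_run(values: np.ndarray, min_tpm: float) -> int:
    best = run = 0
    for v in values:
        run = run + 1 if v > min_tpm else 0
        best = max(best, run)
    return best


def filter_expressed(
    datasets: Sequence[ExpressionDataset],
    min_tpm: float = 0.4,
    run_len: int = 6,
    mode: str = "per_condition",
) -> list[str]:
    """Expressed-gene filter over one or more library types.

    A gene passes iff in *each* dataset some qualifying sample sequence
    contains >= ``run_len`` consecutive values strictly greater than
    ``min_tpm``.  With ``mode="per_condition"`` (default) the run must lie
    within a single condition's time series; with ``mode="pooled"`` the
    samples are interleaved in time order (UIC then MO at each timepoint)
    and the run may span conditions.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    universe = set(datasets[0].gene_ids)
    for ds in datasets[1:]:
        if set(ds.gene_ids) != universe:
            raise ValueError("datasets must share the same gene universe")
    if mode not in ("per_condition", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    for ds in datasets:
        n_avail = ds.timepoints.size if mode == "per_condition" else 2 * ds.timepoints.size
        if run_len > n_avail:
            raise ValueError(f"run_len={run_len} exceeds available sample count {n_avail}")
    passing = []
    for gene in sorted(universe):
        ok_all = True
        for ds in datasets:
            gi = ds.gene_ids.index(gene)
            if mode == "per_condition":
                ok = any(_max_run(ds.tpm[gi, :, ci], min_tpm) >= run_len for ci in range(2))
            else:
                # time-ordered interleave: UIC then MO at each timepoint
                ok = _max_run(ds.tpm[gi].reshape(-1), min_tpm) >= run_len
            if not ok:
                ok_all = False
                break
        if ok_all:
            passing.append(gene)
    return passing
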