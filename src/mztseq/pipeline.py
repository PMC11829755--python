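"""End-to-end orchestration: filter -> GP LR test -> cluster -> enrichment.

A single config drives every stage with reproducible seeds; each run
writes stage outputs plus a machine-readable manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import DEFAULT_SEED, mode_of_selected_k, normalize_trajectories, silhouette_select_k
from .expression import CONDITIONS, filter_expressed, read_tpm_table
from .gp import HyperPriors, lr_test, null_lr_threshold
from .simulate import ClusterSpec, SimulationConfig, simulate_timecourse
from .utr import ELEMENT_MOTIFS


@dataclass
class PipelineConfig:
    """All tunables with their defaults (the values used by the study design)."""

    # intake / filter
    min_tpm: float = 0.4
    run_len: int = 6
    filter_mode: str = "per_condition"
    # VST
    alpha: float = 1.0
    beta: float = 1000.0
    # GP priors (log-space normal)
    prior_mean_log_sigma_f: float = 0.0
    prior_sd_log_sigma_f: float = 1.0
    prior_mean_log_tau: float = float(np.log(2.5))
    prior_sd_log_tau: float = 0.5
    prior_mean_log_sigma_n: float = -1.5
    prior_sd_log_sigma_n: float = 1.0
    n_restarts: int = 5
    # LR threshold calibration
    null_rate: float = 0.005
    null_n_sim: int = 200
    # clustering
    k_min: int = 2
    k_max: int = 10
    cluster_seed: int = DEFAULT_SEED
    # enrichment
    n_max: int = 6
    # global
    seed: int = DEFAULT_SEED
    simulate: bool = True
    sim_n_genes: int = 60
    sim_noise_cv: float = 0.1
    expression_tables: dict = field(default_factory=dict)  # library_type -> path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def priors(self) -> HyperPriors:
        return HyperPriors(
            self.prior_mean_log_sigma_f, self.prior_sd_log_sigma_f,
            self.prior_mean_log_tau, self.prior_sd_log_tau,
            self.prior_mean_log_sigma_n, self.prior_sd_log_sigma_n,
        )

    def validate(self, n_timepoints: int | None = None) -> None:
        if n_timepoints is not None and self.run_len > n_timepoints:
            raise ValueError(f"run_len={self.run_len} exceeds n_timepoints={n_timepoints}")
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("need 2 <= k_min <= k_max")


def _default_sim_config(cfg: PipelineConfig) -> SimulationConfig:
    n_planted = max(6, cfg.sim_n_genes // 4)
    return SimulationConfig(
        n_genes=cfg.sim_n_genes,
        cluster_spec=[
            ClusterSpec("U1", n_planted, "maternal_decay", onset=2.0, effect=6.0),
            ClusterSpec("D1", n_planted, "zygotic_sigmoid", onset=4.0, effect=0.2),
        ],
        noise_cv=cfg.sim_noise_cv,
        seed=cfg.seed % (2**31),
    )


def run_pipeline(config: PipelineConfig, outdir, sim_config: SimulationConfig | None = None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed, "parameters": asdict(config)}

    # ---- inputs
    if config.simulate:
        sim_config = sim_config or _default_sim_config(config)
        config.validate(sim_config.n_timepoints)
        datasets, truth = simulate_timecourse(sim_config)
        truth.to_json(outdir / "truth.json")
        for lib, ds in datasets.items():
            ds.write_tsv(outdir / f"expression_{lib.replace('+', 'plus')}.tsv")
    else:
        datasets = {
            lib: read_tpm_table(path, lib) for lib, path in config.expression_tables.items()
        }
        for path in config.expression_tables.values():
            manifest.setdefault("input_hashes", {})[str(path)] = hashlib.sha256(
                Path(path).read_bytes()
            ).hexdigest()
        first = next(iter(datasets.values()))
        config.validate(first.timepoints.size)

    # ---- expressed-gene filter
    ds_list = list(datasets.values())
    passing = filter_expressed(ds_list, config.min_tpm, config.run_len, config.filter_mode)
    (outdir / "expressed_genes.txt").write_text("\n".join(passing) + "\n")

    # ---- LR threshold from null simulation
    priors = config.priors()
    threshold = null_lr_threshold(
        n_sim=max(100, config.null_n_sim), rng_seed=config.seed % (2**31),
        rate=config.null_rate, priors=priors, noise_cv=config.sim_noise_cv,
        n_timepoints=ds_list[0].timepoints.size, n_restarts=config.n_restarts,
    )
    manifest["lr_threshold"] = threshold

    # ---- GP LR tests, per library type
    selected_ks = []
    summaries = []
    for lib, ds in datasets.items():
        rows, medians = [], {}
        for i, gene in enumerate(ds.gene_ids):
            if gene not in passing:
                continue
            res = lr_test(
                gene, ds.timepoints, ds.tpm[i, :, 0], ds.tpm[i, :, 1],
                priors=priors, gene_max=float(ds.gene_max[i]),
                alpha=config.alpha, beta=config.beta,
                seed=(config.seed + i) % (2**31), n_restarts=config.n_restarts,
                lr_threshold=threshold,
            )
            rows.append({
                "gene_id": gene, "L_U": res.L_U, "L_M": res.L_M, "L_UM": res.L_UM,
                "LR": res.LR, "direction": res.direction, "called": res.called,
            })
            medians[gene] = (res.uic_fit.median, res.mo_fit.median)
        de = pd.DataFrame(rows)
        tag = lib.replace("+", "plus")
        de.to_csv(outdir / f"differential_{tag}.tsv", sep="\t", index=False)

        # ---- clustering per direction
        cluster_labels: dict[str, str] = {}
        for direction, prefix in (("increased", "U"), ("decreased", "D")):
            sub = de[(de.direction == direction) & de.called]["gene_id"].tolist()
            if len(sub) <= config.k_max:
                continue
            feats = normalize_trajectories(
                sub,
                np.vstack([medians[g][0] for g in sub]),
                np.vstack([medians[g][1] for g in sub]),
            )
            k_star, assignment = silhouette_select_k(
                feats, range(config.k_min, config.k_max + 1),
                rng_seed=config.cluster_seed, direction_prefix=prefix,
            )
            selected_ks.append(k_star)
            cluster_labels.update(assignment.labels)
            pd.DataFrame(
                {"k": list(assignment.silhouette_by_k),
                 "silhouette": list(assignment.silhouette_by_k.values())}
            ).to_csv(outdir / f"silhouette_{tag}_{direction}.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"gene_id": g, "cluster": c} for g, c in sorted(cluster_labels.items())]
        ).to_csv(outdir / f"clusters_{tag}.tsv", sep="\t", index=False)

        summaries.append({
            "library_type": lib,
            "n_filtered": len(passing),
            "n_called": int(de.called.sum()),
            "n_increased": int(((de.direction == "increased") & de.called).sum()),
            "n_decreased": int(((de.direction == "decreased") & de.called).sum()),
            "n_clusters": len(set(cluster_labels.values())),
        })

    if selected_ks:
        manifest["selected_k"] = selected_ks
        manifest["k_mode"] = mode_of_selected_k(selected_ks)
    pd.DataFrame(summaries).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return outdir


def report_summary(run_dir) -> pd.DataFrame:
    """Summary table of a completed run (counts by direction, clusters)."""
    run_dir = Path(run_dir)
    path = run_dir / "summary.tsv"
    if not path.exists():
        raise FileNotFoundError(f"incomplete run: {path} missing")
    return pd.read_csv(path, sep="\t")
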