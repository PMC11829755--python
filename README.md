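# mztseq

Temporal differential-expression analysis for two-condition developmental
RNA-seq time courses, built around the maternal-to-zygotic transition
(MZT): which maternally deposited transcripts fail to be cleared when a
perturbation (here, Nup107 depletion by morpholino) disrupts the
machinery — prominently the miR427/miR430 pathway — that degrades them?

The package is aimed at developmental transcriptomics groups who profile
uninjected-control (UIC) versus morphant (MO) embryos at dense, regular
timepoints (e.g. every 30 min across gastrulation) with both polyA+ and
ribozero library preparations, and want a reproducible, fully offline
pipeline from TPM tables to clustered trajectories and clearance-motif
enrichment.

## What it computes

1. **Expressed-gene filter** — keep genes with a run of 6 consecutive
   samples at TPM > 0.4 in each library type.
2. **GP temporal differential expression.** Per gene, abundances x are
   transformed with a variance-stabilizing transform
   f(x) = log2((x + α) / (mᵢ + β)) with α = 1, β = 1000 and mᵢ the gene's
   maximum abundance, placing all genes on one scale. An exact Gaussian
   process with Matérn-5/2 kernel
   k(r) = σ_f² (1 + √5·r/τ + 5r²/3τ²) e^(−√5·r/τ) plus noise σ_n² is fit
   by MAP in log space (normal hyperpriors; L-BFGS then Nelder–Mead).
   Evidence for condition-specific trajectories is the marginal
   log-likelihood ratio **LR = L_U + L_M − L_UM** (separate UIC and MO
   fits versus one pooled fit), called at a null-calibrated threshold.
3. **Trajectory clustering** — GP medians max-normalized per gene (shared
   UIC/MO max), k-means with seed 1618033, k selected by maximal mean
   silhouette over k = 2..10, separately for increased and decreased genes.
4. **3′-UTR enrichment** — EDEN/ARE/YTHDF2 element motifs and all miRNA
   seeds (canonical 7-mer, offset 6-mer, extended 8-mer, in transcriptome
   space) tested per cluster by right-tail Fisher exact tests on
   "≥ N copies", with each seed's minimal mismatch distance to the
   extended miR427 seed AAAGCACTTTC.
5. **Promoter PWM enrichment** — log2 likelihood-ratio scores against
   genomic base frequencies over 500-bp promoters; per-motif threshold
   (> 5) optimized by Fisher association with cluster membership.
6. **Repetitive-locus quantification** — multi-mapping reads retained for
   the ~100-kb miR427 locus, 1/N fractional coverage piles, and mature
   miR427-length fragment detection from adapter read-through read pairs.

A synthetic-data generator (`mztseq.simulate`) produces every input with
planted ground truth, so the entire pipeline is testable with no
downloads.

## Worked example

```python
import numpy as np
from mztseq import (ClusterSpec, SimulationConfig, simulate_timecourse,
                    lr_test, null_lr_threshold)

cfg = SimulationConfig(
    n_genes=4,
    cluster_spec=[ClusterSpec("U1", 2, "maternal_decay", onset=2.0, effect=6.0)],
    noise_cv=0.1, seed=11, library_types=("polyA+",),
)
ds = simulate_timecourse(cfg)[0]["polyA+"]
for i, gene in enumerate(ds.gene_ids):
    res = lr_test(gene, ds.timepoints, ds.tpm[i, :, 0], ds.tpm[i, :, 1],
                  gene_max=float(ds.gene_max[i]), seed=i)
    print(f"{gene}  LR = {res.LR:8.2f}  direction = {res.direction}")
```

prints

```
g00000  LR =    40.89  direction = increased
g00001  LR =    47.72  direction = increased
g00002  LR =   -14.69  direction = increased
g00003  LR =   -14.74  direction = decreased
```

The two planted clearance-blocked genes (maternal decay in UIC, clearance
blocked in MO from 2 h) show overwhelming evidence for separate
trajectories, in the "increased" direction expected for stabilized
maternal transcripts.  The two null genes have negative LR (the pooled
model is preferred) and fall far below any null-calibrated threshold;
`null_lr_threshold` computes that threshold as an upper quantile of LR
over simulated null genes.

The same stages run from the shell:

```sh
mztseq run-all --seed 1618033 --outdir run/
mztseq locus alignments.bed --outdir locus_out/
```

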