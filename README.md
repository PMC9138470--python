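# cdrflex

Conformational-entropy analysis of antibody loop ensembles.

Single-domain antibodies (sdAbs, nanobodies) bind antigen through their
hypervariable loops, above all the CDR3. How floppy that loop is — how many
distinct conformations it populates, and with what probabilities — shapes
both binding affinity (an entropic penalty is paid on rigidification) and
the comparison between designed and immune-derived antibodies. `cdrflex`
turns an ensemble of conformations produced by enhanced-sampling molecular
dynamics into quantitative flexibility measures, for computational
antibody designers and MD practitioners.

## What it computes

Given a multi-model PDB ensemble, a PLUMED COLVAR-style table of per-frame
bias potentials, and the CDR/HV loop definitions:

1. **Metadynamics reweighting.** Parallel-bias metadynamics samples a
   biased distribution; unbiased Boltzmann statistics are recovered with
   per-frame weights

   $$w_i = \frac{\exp(V_{PB,i}/k_B T)}{\sum_j \exp(V_{PB,j}/k_B T)}$$

   and every downstream observable is a weighted ensemble average.
2. **Conformational clustering.** Pairwise loop-Cα RMSD (optimal
   superposition per pair) feeds either GROMOS/Daura clustering (iteratively
   peel off the frame with the most neighbours within a cut-off, default
   0.15 nm) or average-linkage hierarchical clustering.
3. **Cluster entropy.** The heterogeneity metric
   $S = -\sum_i p_i \ln p_i$ over weighted cluster populations, with a
   weighted bootstrap (20 samples of 10,000 frames drawn with probability
   $w$, re-clustered independently) providing 95th-percentile error bars.
4. **Ramachandran entropy.** Per-residue $S = -\sum_{jk} p_{jk}\ln p_{jk}$
   over a weighted 100×100 histogram of (φ, ψ).
5. **Contact landscapes.** Heavy-atom residue contacts (< 0.45 nm), contact
   probability maps, per-residue RMSF, and a 2D free-energy surface
   $F = -k_B T \ln(p/p_{max})$ over the relative proportions of intra-CDR3
   and CDR3–scaffold contacts.
6. **Convergence diagnostics.** Split-half comparison of cluster
   populations after discarding the first 10% of frames, judged against
   bootstrap population errors with a 0.001 population floor.

A synthetic-data module generates multi-basin ensembles with known basin
populations, bias values and dihedral statistics — ground truth for every
stage — and writes them in the pipeline's own input formats.

## Worked example

Generate a synthetic 3-basin ensemble whose loop populates basins with
probabilities 0.6/0.3/0.1 once reweighted, then run the full pipeline:

```bash
cdrflex simulate --basins 3 --populations 0.6,0.3,0.1 --frames 2000 \
        --bias-mode reweight-to-target --seed 7 --out-dir demo
cdrflex run --ensemble demo/ensemble.pdb --bias demo/colvar.dat \
        --regions demo/regions.txt --output demo_run --seed 1
```

The run directory contains weights, cluster assignments, entropy JSON,
per-residue dihedral entropies, contact maps, RMSF, the free-energy
surface, a convergence report and a manifest. For this seed:

```
clusters:  3  populations [0.6008, 0.2945, 0.1047]
entropy:   0.9024 nats   bootstrap 95% band [0.8793, 0.9175]
converged: True
```

The three clusters recover the constructed basin populations to within
sampling error, and the cluster entropy matches the analytic
$-\sum p\ln p = 0.8979$ nats inside the bootstrap band. The effective
sample size printed by the weights stage (1437 of 2000 frames) quantifies
how uneven the metadynamics weights are.

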