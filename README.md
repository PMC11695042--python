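# blockpls

Multiblock partial least squares with block-importance statistics for
genotype–phenotype mapping.

Quantitative phenotypes of microbial strains (the motivating case:
growth efficiency and rate of *Saccharomyces cerevisiae* under chemical
stress) often depend on groups of correlated genes rather than single
loci, and the data come as a short, wide matrix: tens of genomes, 
thousands of per-gene scores. `blockpls` is a toolchain for this
regime. It

- discovers **gene blocks** by k-means over variables, choosing the
  number of blocks with the silhouette index;
- fits a **modified multiblock PLS** in which each block's score is
  normalized by the block size, so large blocks cannot dominate the
  latent components;
- ranks blocks with **BIP** (block importance on projection) and the
  weighted variant **BwIP**, which additionally penalizes large diffuse
  blocks:

      BIP(c)  = C Σ_r cov²(y, t_r) w_r(c)²        / Σ_r cov²(y, t_r)
      BwIP(c) = C Σ_r cov²(y, t_r) U_r(c) w_r(c)² / Σ_r cov²(y, t_r)

  with U_r(c) = ‖u_r(c)‖²/p_c; mean BIP over blocks is exactly 1, so
  BIP > 1 flags influential blocks;
- selects genes within retained blocks by **VIP** (VIP > 1) or absolute
  loading weight (> 0.2);
- provides **plain PLS**, **mbPLS** and a **group lasso** over the same
  partition as baselines, all under one cross-validated pipeline with
  calibrated (training) and validated (held-out, selection-inside-CV)
  RMSE;
- generates **synthetic blocked data** (Cholesky-correlated blocks,
  sparse uniform coefficients, Gaussian noise) for power studies and a
  method-comparison benchmark.

See `docs/methods.md` for the algorithms, conventions and limitations.

## Worked example

Generate a blocked dataset whose signal lives in block 2, then run the
BwIP-guided pipeline:

```python
import blockpls as bp

cfg = bp.SimConfig(n=100, block_sizes=(20,) * 6, active_blocks=(2,),
                   snr=4.0, seed=3)
sim = bp.generate(cfg)

result = bp.run_pipeline(
    sim.to_dataset(), sim.partition(),
    bp.PipelineConfig(method="bwip-mbpls", seed=1),
)
print("selected blocks:   ", result.selected_blocks)
print("selected genes:    ", result.selected_variable_ids)
print("components (trace):", result.component_trace)
print("calibrated RMSE:   ", round(result.calibrated_rmse, 3))
print("validated  RMSE:   ", round(result.validated_rmse, 3))
```

Output:

```
selected blocks:    [2]
selected genes:     ['g23', 'g29', 'g32', 'g33', 'g36', 'g38']
components (trace): [4, 9, 3]
calibrated RMSE:    1.624
validated  RMSE:    1.839
```

The pipeline recovers the active block and keeps 6 genes inside it —
all 4 planted coefficients (g23, g32, g36, g38) plus two correlated
neighbours picked up by VIP — and settles on 3 latent components after
the final filtering stage. The validated RMSE sits near the noise floor
(σ ≈ 1.72 at SNR 4 for this draw), while a plain PLS on the same data
validates around 2.1.

The same workflow from the shell:

```sh
blockpls simulate --seed 3 --out data/
blockpls cluster --input data/X.csv --k-min 2 --k-max 10 --seed 1 --out partition.csv
blockpls select --x data/X.csv --y data/y.csv --blocks data/blocks.csv \
                --method bwip-mbpls --folds 10 --seed 1 --out result.json
blockpls benchmark --replicates 50 --seed 1 --out benchmark.csv
```

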