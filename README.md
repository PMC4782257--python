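# morphoevo

Phylogenetic geometric morphometrics for 2D landmark data: a tested,
reusable pipeline for asking whether the more *variable* parts of a
structure (e.g. the mammalian skull) are also the more *labile* ones —
the ones most capable of responding to selection — or whether their
diversity instead reflects faster evolutionary rates or weaker
constraint.

It is aimed at comparative morphologists who have landmark/semi-landmark
configurations (TPS files) for a sample of species and a time-calibrated
phylogeny (Newick), and who want, per anatomical region:

* **Shape variables** — Generalized Procrustes Analysis (GPA) with
  thin-plate-spline semi-landmark sliding by bending-energy minimisation,
  and orthogonal projection into the tangent space at the mean shape.
* **Allometry** — multivariate regression of phylogenetic independent
  contrasts (PIC) of shape on PIC of log centroid size, a permutation test
  of its significance, and conditional size correction of the species data.
* **Evolutionary model fits** — Brownian motion (BM), single-optimum
  Ornstein–Uhlenbeck (OU, constraint strength α), early burst (EB, rate
  exponent ρ), Pagel's δ depth-power transform, and a combined δ+OU model,
  compared by AIC under a pooled multivariate likelihood; the multivariate
  rate σ²mult; morphological disparity P² (mean squared tangent distance).
* **Lability indexes** — the ancestral P-matrix (covariance of
  reconstructed internal-node shapes), mean-standardized, probed with
  random skewers: respondability r̄ = E‖Pβ‖, evolvability ē = E[βᵀPβ]
  and flexibility f̄ = E[cos(Pβ, β)] for unit selection gradients β.
* **Synthetic data** — a generator that simulates pure-birth trees,
  trait evolution under any of the models above with known parameters,
  and raw TPS files with injected allometry and digitisation nuisance, so
  every stage is testable against ground truth.

The core statistical machinery follows the standard comparative-methods
formulation: under BM the among-species covariance is the shared-ancestry
matrix **C** (C[i,j] = root-to-MRCA path length); each model rescales
**C** (δ: `T^{1-δ} C^δ`; EB: `(e^{ρC}-1)/ρ`; OU on an ultrametric tree:
`e^{-2α(T-s)}(1-e^{-2αs})/(2α)`), and p independent traits share one
pooled rate, profiled out analytically together with the GLS root state.
Ancestral states are the branch-length-weighted squared-change-parsimony
(equivalently maximum-likelihood) reconstructions.

## Worked example

Simulate a 100-species cranium dataset in which the face region evolves
at twice the per-trait rate of the braincase (0.010 vs 0.005 per unit
tree depth, six traits each, ~2.3% injected allometry), then run the full
pipeline on the raw files:

```python
import morphoevo as me

cfg = me.SimulationConfig(n_tips=100, seed=11, n_traits=6)
ds = me.simulate_dataset(cfg, region_sigma2={"face": 0.010, "braincase": 0.005})
paths = ds.write("demo")                      # landmarks.tps, tree.nwk, truth.txt

pc = me.PipelineConfig(
    tps_paths={"cranium": str(paths["tps"])},
    newick_path=str(paths["newick"]),
    templates={"cranium": "cranium19"},
    partition={r: me.RegionSpec("cranium", ds.template.region_partition[r])
               for r in ("face", "braincase")},
    n_permutations=10000, n_skewers=1000, seed=0)
results, provenance = me.run_pipeline(pc)
print(me.compare_regions(results, "face", "braincase"))
```

which prints (abridged):

```
   region  n_species  pct_var_size  p_size best_model      P2  sigma2_mult  flexibility
     face        100         3.156  0.0034         BM 0.04048     0.008509       0.2106
braincase        100         1.923 0.06339         BM 0.02166      0.00375       0.2518

P2                1.87
sigma2_mult       2.27
```

Reading the output: the injected allometry is detected in the face
(3.2% of shape variance, permutation p = 0.0034, so size correction is
applied there), disparity P² and the multivariate rate σ²mult are about
twice as large in the face as in the braincase — recovering the simulated
2:1 contrast — and the flexibility of the two regions' ancestral
P-matrices is similar, as expected when both regions receive the same
number of independent trait dimensions.

A `morphoevo` command-line tool exposes the same functionality
(`morphoevo simulate`, `morphoevo run --config config.yaml`,
`morphoevo fit`, `morphoevo skewers`).

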