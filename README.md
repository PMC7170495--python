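# dyncross

Dynamic gene-expression analysis of pathway cross-talk in four-condition
time-course transcriptomics.

When a cell line is profiled over time under a control condition, two
single stimulations (Sonic Hedgehog, SHH; epidermal growth factor, EGF)
and their co-stimulation (EGF+SHH), the interesting biology is not in any
single time point but in how whole expression *trajectories* change
between conditions.  `dyncross` implements that analysis end to end for
anyone working with designs of this shape (n genes × K time points × N
replicates per condition):

1. **Dynamic response genes (DRGs).**  Each gene's replicate-median,
   fold-change, centered profile `Y(t_k) − μ = X(t_k) + E(t_k)` is
   smoothed with a penalized natural cubic spline (λ by generalized
   cross-validation over a fixed grid) and tested against
   `H₀: X(t) ≡ 0` with the functional F-ratio

   `F = [(RSS₀ − RSS₁)/(edf − 1)] / [RSS₁/(K − edf)]`,

   with p-values from a permutation null (time-label shuffling; exact
   under i.i.d. noise) by default, Benjamini–Hochberg adjusted.
2. **Gene response modules (GRMs).**  DRGs are clustered by iterative
   hierarchical clustering (IHC): average-linkage seeding on the distance
   `1 − ρ_Spearman`, then repeated merge / reassign / recenter passes at
   the similarity threshold ρ ≥ 0.7.  GRM1 is the largest module.
3. **Gene regulatory network (GRN).**  Module mean curves enter sparse
   linear rate equations `dM_q/dt = α₀q + Σ_p α_pq M_p`; per target,
   support is selected by best-subset search scored with an extended BIC
   and the coefficients are refit by OLS.  Positive coefficients read as
   stimulation, negative as inhibition.
4. **Network statistics.**  In/out-degree, unnormalized betweenness
   `Bet(v) = Σ_{s≠t} σ_st(v)/σ_st`, density and mean clustering
   coefficient; "important" modules rank in the top 20 (or 95th
   percentile) of any criterion.
5. **Cross-talk / co-activation screening.**  A gene shows *differential
   activity* between conditions when its curves' Spearman ρ falls below
   0.7, and *significant variation* when its range reaches 1.96 on the
   standardized fold-change scale.  Cross-talk genes respond to both
   single stimuli but follow a different trajectory under co-stimulation;
   co-activation genes respond only under co-stimulation.  Screening is
   two-stage: module mean curves first, then the genes inside qualifying
   modules.

A fully seeded synthetic-data generator (`dyncross.synthetic`) emulates
the study design — 14 time points over 24 h, 3 replicates, centered log2
fold-change values — with planted ground truth for every stage, so the
entire pipeline is testable without any download.

## Worked example

```python
from dyncross.synthetic import SimulationConfig, simulate_study
from dyncross.pipeline import PipelineConfig, run_all, summarize

cfg = SimulationConfig(n_genes=500, n_dynamic=300,
                       n_crosstalk=20, n_coactivation=10, seed=5)
study, truth = simulate_study(cfg)
run_all(PipelineConfig(min_module_size=40, seed=5), "runs/demo", study=study)
print(summarize("runs/demo"))
```

prints (abridged):

```
condition  n_drg  n_grm  grm1_size  frac_first_6   density  mean_clustering_coefficient
     CTRL    281      9         54      0.989324  0.236111                     0.251852
      SHH    308     12         55      0.944805  0.196970                     0.163889
      EGF    305     12         54      0.950820  0.136364                     0.225000
  EGF_SHH    306     13         54      0.947712  0.121795                     0.282051
```

Of the 500 genes, ~300 planted dynamic genes are detected per condition
(`n_drg`); they fall into 9–13 temporal modules of which the largest
(`grm1_size`) holds ~55 genes; `frac_first_6` is the fraction of
detected genes inside the six largest modules; the last two columns
summarize the inferred module network.  The cross-talk report in
`runs/demo/08_crosstalk/` recovers the planted cross-talk and
co-activation genes.

The same stages are exposed on the command line:

```
dyncross simulate --n-genes 500 --n-crosstalk 20 --seed 5 --out data/
dyncross run --config config.yaml --out runs/exp1
dyncross summarize runs/exp1
```

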