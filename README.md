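# cascadefit

Bayesian modeling of gene expression dynamics along pseudotime trajectories.

During differentiation, cells traverse a continuum of states that
single-cell RNA-seq can capture as a pseudotime ordering.  `cascadefit`
answers the questions that orderings alone leave open: *when* along the
trajectory is each gene switched on or off, with what uncertainty, in what
order do those switches occur, and which timing patterns are consistent
with one gene regulating another?  It is aimed at computational biologists
who already have a pseudotime-ordered UMI count matrix (from diffusion
pseudotime, Slingshot, Monocle, ...) and want an explicit, probabilistic
ordering of transcriptional events — e.g. the transcription-factor cascades
that drive cortical neurogenesis or pancreatic beta-cell maturation.

## Model

For a gene g with counts y_gt in cells t = 1..N (ordered by pseudotime),
the likelihood is negative binomial with a global dispersion φ,

    y_gt ~ NB(μ_gt, φ),    Var[y] = μ + μ²/φ,

where μ_gt = h⁻¹(f_α(t; θ)) maps a response curve f_α from log-normalized
fit space back to counts (h(y) = ln(y·M̃/M_t + 1), with M_t the cell's UMI
total and M̃ the dataset median).  Four curve families α cover the dynamics
of interest:

| family | form | pattern |
|---|---|---|
| uniform | b | no dynamics |
| Gaussian | a·exp(−(t−t0)²/(2σ²)) + b | transient impulse |
| sigmoidal | L/(1+e^{−k(t−t0)}) + b_min | state switch (k may be < 0) |
| double sigmoidal | b_min + (b_mid−b_min)/(1+e^{−k1(t−t1)}) + (b_max−b_mid)/(1+e^{−k2(t−t2)}) | asymmetric impulse / stepwise |

Posteriors over θ are sampled with an affine-invariant ensemble MCMC (four
walkers per parameter, stretch moves); the best family is chosen by BIC at
the posterior-mean parameters evaluated on 10,000 random 98% subsets of the
cells, with branch rules that prefer simpler families.  Signed inflection
points — t0±σ for the Gaussian, t0 for the sigmoid, t1 and t2 for the
double sigmoid — are extracted from every posterior draw, giving each gene
a full posterior over its switch times.  Genes are ordered by the median of
their first inflection time; pairs of genes are compared through the
histogram overlap P(A=B) = Σᵢ min(p_A(xᵢ), p_B(xᵢ)) of their inflection
samples, which drives the regulatory-interaction rules and the
upstream-regulator screen.  See `docs/methods.md` for the full treatment.

## Worked example

Simulate a 300-cell trajectory with known response curves and fit one gene
(here a state switch with true t0 = 178.1, generated at seed 3):

```python
import cascadefit as cf

specs = cf.benchmark_gene_specs(1, 300, seed=3)     # one gene per family
cfg = cf.SimulationConfig(n_cells=300, phi=10.0, gene_specs=specs, seed=1)
cm, pt, truth = cf.make_benchmark_dataset(cfg)
td = cf.build_trajectory(cm, pt)

res = cf.fit_gene(td, "sig000", phi=10.0, n_iterations=2000,
                  burn_in=1000, n_subsets=500, seed=7)
print(res.summary())
```

```
================================================================
                  Gene expression dynamics fit
================================================================
Gene: sig000    N cells: 300    phi: 10
Best family: sigmoidal    (selection branch: sigmoidal)
Dynamic class: state_switch_up
----------------------------------------------------------------
Subsample BIC  mean [min, max]  (n_sub = 294)
  uniform                1263.19 [   1240.45,    1274.11]
  gaussian                798.72 [    781.60,     811.35]
  sigmoidal               772.24 [    757.19,     784.88]
  double_sigmoidal        798.84 [    785.51,     810.14]
----------------------------------------------------------------
Posterior mean +/- sd
  k            0.0688 +/- 0.0199
  L            1.5295 +/- 0.0737
  t0         178.0722 +/- 3.7632
  bmin         0.1813 +/- 0.0368
Inflection points (median [95% CI], sign)
  t =   177.93 [  171.15,   185.58]  (+)
Acceptance fraction: mean 0.591  min 0.574
================================================================
```

The sigmoidal family wins the subsample-BIC comparison (its worst subset
BIC, 784.9, still beats the uniform's best, 1240.5, and its mean beats the
Gaussian and double-sigmoid means), the gene is classified as an upward
state switch, and the switch time posterior (median 177.9, 95% CI
[171.2, 185.6]) covers the generating t0 = 178.1.  With several fitted
genes, `cf.order_cascade(results)` sorts them into a cascade by first
inflection time and `cf.infer_interaction(a, b)` / 
`cf.screen_upstream_regulators(target, candidates)` derive directed
regulatory calls from the timing and signs.

The same pipeline is available from the shell:

```sh
cascadefit simulate --config sim.yaml --out data/
cascadefit fit --counts data/counts.mtx --genes data/genes.txt \
    --cells data/cells.txt --pseudotime data/pseudotime.tsv \
    --out fits/ --seed 1
cascadefit cascade --fits fits/ --out cascade.tsv
cascadefit regulators --fits fits/ --target Eomes --out regulators.tsv
```

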