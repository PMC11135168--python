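# radpath

Pathway-level analysis of gene expression under graded ionizing-radiation
exposure, for transcriptomics researchers studying low-dose radiation
response.  Given a genes × samples expression matrix, per-sample dose
annotations, and pathway gene sets (GMT), `radpath` ranks pathways whose
member genes shift in a coordinated, dose-dependent way, by two
complementary routes:

1. **Probabilistic LLR scoring.**  For a two-phenotype contrast (e.g.
   unirradiated vs low dose), each gene's expression is modelled as Gaussian
   per phenotype and scored by the log-likelihood ratio
   `L_k(x) = ln f_k^1(x) / f_k^2(x)`.  LLRs are standardised gene-wise,

       L̂_k(x) = (L_k(x) − E[L_k]) / sqrt(E[(L_k − E[L_k])²]),

   class-oriented, and summed over a pathway's members into a per-sample
   activity score `S_j = Σ_k L̂_k(x_{j,k})`.  A pathway's differential
   activity is the mean over member genes of the absolute one-sample t
   statistic of the oriented L̂ against mean 0; pathways are ranked by this
   aggregated score.  (Without the standardisation, the sign of the summed
   LLR is exactly an equal-prior naive Bayes decision.)

2. **Pathway-masked variational autoencoder.**  A VAE whose linear decoder
   is masked by gene–pathway membership (latent dimension = n_pathways + 1,
   the extra node fully connected), so each latent unit is readable as one
   pathway's activity.  Differential activity between two dose groups is
   scored by a Monte-Carlo Bayes factor `BF = ln P/(1−P)` with
   `P = Pr(z₁,p > z₂,p)` over sampled posterior pairs; `|BF| ≥ ln 10 ≈ 2.3`
   marks significance.

Around these sit dose-design experiment drivers (per-dose contrasts,
progressive inclusion of low-dose groups, top-k ranked-list intersection
curves, pooled low-dose joint analysis, fixed-model dose profiles) and a
synthetic-study generator with planted responsive pathways that emulates a
7-dose-level, 121-sample blood irradiation design (0–0.5 Gy, low/high
threshold at 0.1 Gy).

## Worked example

```sh
radpath simulate --n-genes 500 --n-pathways 20 --n-low-responsive 2 \
    --effect-size 1.5 --out study/ --seed 7
radpath analyze-llr --expression study/expression.tsv \
    --annotations study/annotations.tsv --gmt study/pathways.gmt \
    --out results/ --seed 7
head -4 results/llr_ranking_zero_vs_low.tsv
```

```
# radpath 0.1.0 seed=7
pathway_id	name	n_members	aggregated_score	pathway_t	n_samples	p_value	p_adj	rank
path001	synthetic pathway 1	29	2.1085394963816926	4.598251542196501	105	1.2041038253357769e-05	1.852467423593503e-05	1
path000	synthetic pathway 0	39	2.0350567490340135	4.6989718238497655	105	8.03943928696378e-06	1.4617162339934143e-05	2
```

The two pathways planted as low-dose responsive (`path000`, `path001`,
listed in `study/ground_truth.json`) rank first and second of 20.
`aggregated_score` is the mean absolute member-gene t statistic over the
105 contrast samples (18 zero + 87 low dose); `p_value` is the two-sided
Student-t p of the pathway-level score with `p_adj` its Benjamini–Hochberg
adjustment.  `radpath analyze-vega` writes the corresponding Bayes-factor
table (`vega_bf_zero_vs_low.tsv`) and a 2-D UMAP embedding of the latent
space; `radpath intersect` writes top-k intersection curves; `radpath
run-all` produces everything plus a JSON run manifest.

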