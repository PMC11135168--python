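# Methods

## The inference problem

Blood irradiation studies profile gene expression at several absorbed doses
(here emulated as 0, 0.005, 0.01, 0.025, 0.05, 0.1 and 0.5 Gy with
18/16/18/18/17/18/16 samples, 121 in total, from five donors).  Doses at or
below 0.1 Gy are treated as one *low-dose* phenotype, 0.5 Gy as *high
dose*, 0 Gy as the unexposed reference; the 0.1 Gy boundary (inclusive on
the low side) follows radiation-protection convention and is a parameter.
The question is which annotated pathways show coordinated expression shifts
under each exposure regime.

## Probabilistic LLR pathway activity

Per contrast (ZERO vs LOW, or ZERO vs HIGH), each gene k gets two Gaussian
class-conditional densities fitted by the class sample mean and population
(ddof = 0) standard deviation.  The per-gene log-likelihood ratio (natural
log) is standardised gene-wise by its first moment and root second central
moment over the pooled contrast samples — population-style moments, because
the standardisation is defined through expectations — then class-oriented
(class-2 samples negated) so that a genuine difference pushes every
sample's score positive.  Pathway activity is the sum of member-gene
standardised LLRs; the ranking statistic is the mean absolute one-sample
t statistic (sample sd, ddof = 1, the t-test convention) of member-gene
oriented LLRs against mean 0.  The pathway-level one-sample t of the summed
score is computed alongside: the two aggregation readings differ and both
are exposed, with the per-gene reading used for ranking by default.
Two-sided p-values use Student's t with n−1 df; Benjamini–Hochberg adjusted
values are reported alongside (no specific procedure is canonical here).

Numerical guards: every standard deviation (class fits, standardisation,
t denominators) is floored at 1e-6, so constant genes produce finite, zero
scores instead of NaNs.  Ties in rankings break lexicographically by
pathway id.  Gaussian fits and standardisation constants use the same
samples that are scored (in-sample analysis; no cross-validation), and
class priors are equal — the LLR contains no prior term.

Two consequences of in-sample fitting are worth knowing.  First, chance
class-mean differences give even effect-free genes slightly class-favouring
LLRs, inflating small-subset t statistics; this is why the per-step model
is *not* refitted in the progressive-inclusion experiment (below) and why
dose profiles of null pathways are not exactly flat (they show a
zero-vs-low split of a few standard errors at these sample sizes; tests
assert relative, not absolute, flatness).  Second, raw (unstandardised,
unoriented) summed LLRs are exactly an equal-prior Gaussian naive Bayes
decision statistic, which the tests verify against an independent
density-evaluation oracle.

## Dose-design experiments

* **Per-dose scores**: each non-zero dose group is contrasted against the
  zero group independently (refit per dose), with t statistics over that
  dose group's samples — one ranking per dose.
* **Progressive inclusion**: the two-phenotype model is fitted once on the
  full zero-vs-low contrast; step i takes the aggregated t over the pooled
  samples of the first i low-dose groups (ascending from 0.005 Gy, or
  descending from 0.1 Gy).  Holding the model fixed isolates the intended
  phenomenon — t growing with sample size at a fixed effect — rather than
  small-sample refit artefacts, which at these group sizes otherwise
  dominate and reverse the trend.
* **Top-k intersection curves**: count(k) = size of the intersection of all
  included lists' top-k prefixes, k = 1..K.  Multi-list comparisons
  intersect across *all* included experiments.
* **Low-dose joint analysis**: all LOW samples pooled into one contrast
  (identical code path to the generic two-class analysis).
* **Dose profiles**: the zero-vs-low model applied unchanged to samples of
  every dose (including 0.5 Gy); per-dose summed scores are reported with
  positive = dosed-class-like orientation.

## Synthetic studies

The generator realises exactly the model the LLR inference assumes:
baseline gene k is Normal(mu_k, sigma_k) with mu_k ~ Normal(7, 2) and
sigma_k ~ Uniform(0.3, 1.0) drawn once per gene (log-scale microarray-like
values; only effect sizes relative to sigma_k matter downstream).  Member
genes of designated low-responsive pathways receive a mean shift of
`effect_size · sigma_k · c(dose)` where c is 0 at dose 0, monotone
non-decreasing, and 1 at the 0.1 Gy threshold, staying flat above it;
curve shapes are `saturating` (half-maximal at 0.05 Gy, the default),
`linear`, or `step`.  High-responsive pathways switch on only above the
threshold.  The two responsive sets are disjoint by default so the
zero-vs-low and zero-vs-high contrasts have distinct planted answers.
Optional features: additive donor intercepts (5 donors, Normal(0, 0.2))
and a configurable fraction of not-detected cells to exercise the 75%
detection filter.  Everything is bit-reproducible under a seed.

What the generator does **not** emulate: probe-level microarray artefacts,
batch/normalization pipelines, count noise, gene–gene correlation beyond
the planted mean shifts, and the non-monotone per-dose effect profiles real
data can show.  Passing tests therefore demonstrate correctness of the
machinery under the model's own assumptions, not performance on real
arrays.

Note on the step curve: experiments whose premise is a *common* low-dose
effect (progressive inclusion power growth; strong-shift Bayes-factor
checks) use `effect_curve="step"`, matching the inference model's treatment
of all low doses as one phenotype.  Under graded curves the weakest-dose
samples genuinely score reference-like against the pooled low density, and
power comparisons across subsets mix effect heterogeneity with sample size.

## Pathway-masked VAE

Architecture: encoder genes → 800 ReLU units → linear mean and
log-variance heads of dimension n_pathways + 1; decoder is a single linear
layer whose weight from latent unit p to gene g is hard-masked to zero
unless g ∈ pathway p, with the final latent unit dense (catch-all
variability node).  Unit-variance Gaussian reconstruction likelihood on
gene-standardised inputs, standard-normal prior, one reparameterised sample
per input per step.  Training: Adam, learning rate 1e-4, at most 200
epochs, early stopping after 10 epochs without improvement of the
(deterministic, at-the-posterior-mean) monitored loss, best weights
restored; training loss is monitored by default because a held-out split
is noisy at ~100 samples (a validation-fraction option exists).  The
network is implemented directly on numpy arrays with hand-derived
gradients; masked gradients and weights are zeroed after every update, so
the zero pattern is exact (not a penalty) and survives serialization
(single .npz archive with config, gene and pathway order).

Two initialisation/schedule choices matter at this data scale and are the
package's own: (i) sparse decoder rows are initialised with variance 1/fan
over their *active* connections — dense-layer scaling would start a
20-gene pathway row two orders of magnitude too small to train within the
fixed budget; (ii) the KL term is linearly annealed over the first 50
epochs (standard in this model family), without which posteriors stay
pinned to the prior within the 200-epoch, lr 1e-4 budget.  Early stopping
begins counting only once the KL weight reaches 1, since the objective is
still changing during warm-up.  Batch size defaults to 32; analyses of
~100-sample studies benefit from smaller batches (more optimizer updates
under the fixed learning rate and epoch cap) and the Bayes-factor tests use
batch size 4.  Encoder nonlinearity ReLU, no dropout; log-variances are
clipped to ±10 for numerical safety.

**Differential activity.**  For pathway p, draw n pairs (a random class-1
sample's posterior sample, a random class-2 sample's), estimate
P = Pr(z₁,p > z₂,p), clamp P to [1/(n+1), n/(n+1)] to keep the log-odds
finite, and report BF = ln P/(1−P) with significance at |BF| ≥ ln 10 ≈ 2.3.
The sign says which group sits higher; the clamp caps |BF| at ln n (≈ 9.2
at the default n = 10,000).  BF(A,B) = −BF(B,A) up to Monte-Carlo error.
UMAP embeds posterior means in 2-D for visualisation (seeded; the
neighbour count auto-shrinks for tiny inputs).

## Problem sizes in tests and the acceptance script

Simulation-backed checks run at reduced scale chosen to keep the planted
signal unambiguous while the whole suite stays quick: LLR recovery uses
1000 genes × 50 pathways at the full 121-sample design over 10–20 seeds;
VAE checks use 300 genes × 20 pathways (zero + low samples) with 5–10
seeds.  The acceptance script derives every sub-seed from its `--seed`
argument and recomputes each reported quantity from fresh simulations.

## Known limitations

* The LLR route is strictly two-phenotype; multi-class contrasts are out of
  scope.
* The VAE's Gaussian likelihood targets normalized continuous expression;
  count data would need a different reconstruction model.
* In-sample t statistics are optimistic in absolute terms (see above);
  rankings are the supported output, not calibrated effect sizes.
* Bayes factors depend on the stochastic training trajectory; magnitudes
  vary across seeds even when the induced ranking is stable.
* GMT parsing assumes gene identifiers already match the expression matrix;
  no probe-to-gene mapping is performed.
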