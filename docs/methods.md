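# Methods

## Model and assumptions

`screensim` models a loss-of-function pooled CRISPR screen as a
two-arm count experiment. The quantities below are all on the log2
fold-change (LFC) scale unless noted.

**Gene effects.** Non-essential genes have effect exactly 0. Essential
gene effects are `s · X` with `X` drawn from a normal with mean −1.2
and variance 5, truncated above at −0.7, and `s` the effect
multiplier. The mean and variance parameterize the *parent* normal:
the realized mean of the truncated draws is therefore more negative
than −1.2 (about −2.68 before the multiplier at the defaults). The truncation excludes
weak-effect genes from the positive class while keeping the long
negative tail seen in real essentiality screens; the multiplier scales
location, spread, and bound together, emulating lower-signal screens.

**Guide effects and efficiency.** Each targeting guide binds with
probability `guide_efficiency` (i.i.d. Bernoulli). Binding guides draw
their effect from `N(gene effect, 0.1)`; non-binding guides draw from
the null distribution, which we define as `N(0, 0.1)` — the same
guide-level variance centered at zero — so dead guides, null-gene
guides, and negative controls are exchangeable. The probability that
an essential gene has no working guide is `(1 − π)^g` (0.32768 at
π = 0.2, g = 5), which bounds the recall any analysis method can
reach.

**Abundance and counts.** Every guide receives one latent relative
abundance `A ~ Gamma(1, 1)` shared by all samples: it represents
library-representation (cloning) variability, which is common to both
arms and all replicates. Counts are `Poisson(A · d · ε)` with
sequencing depth `d` and technical noise `ε ~ Gamma(1, 1)` drawn
independently per guide × sample. Marginally `E[count] = d` and
`Var[count] = d + 3d²`: the gamma mixing makes counts strongly
overdispersed, as in real screens. Treated-arm abundance is
`A · 2^(guide effect)`, renormalized to mean exactly 1 before the same
depth-and-noise count draw — effects are applied at the guide level
(per-guide effects would otherwise be unused) and on the linear scale
via `2^effect`, since effects are log2 fold changes.

**Replicates.** `n_replicates` (default 2 per arm) controls how many
independent noise-and-Poisson draws share the single latent abundance
vector. Two is a deliberately modest default typical of genome-scale
screens; the number materially affects the tail behaviour of the null
LFC distribution (see "Known limitations").

**Randomness.** One root seed spawns independent child streams per
stage (gene effects, binding masks, abundance, one per count sample),
so changing the replicate count does not perturb the effect draws, and
parameter-sweep cells derive their seeds by hashing (root seed,
parameter, value, replicate) — every cell is reproducible in
isolation.

## Analysis methods

**LFC estimation.** Counts are normalized by median-of-ratios size
factors (rescaled to geometric mean 1), averaged per arm, and the
per-guide LFC is `log2((mean treated + 0.5) / (mean initial + 0.5))`.
The pseudocount of 0.5 keeps LFCs finite at zero counts without
materially biasing well-covered guides at the default depth of 100.
LFCs are centered so the median of the negative controls (or of all
guides, as a logged fallback) is 0 — the standard assumption that the
bulk of guides is null. This is a deliberately transparent stand-in
for a moderated count-model LFC estimator; exact numerical agreement
with count-GLM pipelines is not claimed.

**Pooled t-test.** Each gene's guide LFCs are compared to the control
LFCs with a two-sided pooled-variance t-test (df = n₁ + n₂ − 2),
defined even at one guide per gene; the pooled variance is floored at
1e−12 to avoid 0/0 on degenerate inputs. FDRs are Benjamini-Hochberg.
The method requires control guides and refuses to run without them.

**RSA-style rank statistic.** Targeting guides are ranked by
increasing LFC (most depleted first; ties broken by guide id). A
gene's p-value is the minimum over its guides `i = 1..k` of
`P(X ≥ i)` for `X ~ Hypergeometric(M, k, r_i)`, i.e. the strongest
enrichment of the gene's guides in any top-of-list prefix. The minimum
is taken uncorrected, matching the statistic's classical description;
under the null it is therefore anti-conservative by up to a factor of
`k` (union bound), which the test suite verifies empirically. Only
ranks enter the statistic, so a single outlier guide cannot carry a
gene. The per-screen path computes the hypergeometric tail with a
log-gamma sum over at most `k` terms (scipy's distribution object is
the cross-check oracle in the tests, but is orders of magnitude slower
over ~100k guides).

**Stouffer combination.** Guides are z-scored against the control LFC
mean and standard deviation (all targeting guides, with a logged
warning, when fewer than two controls exist) and combined per gene as
`z = Σzᵢ/√n`, reported as a two-sided p-value. The scalar
`stouffer_combine` takes two-sided p-values with direction signs and
halves them internally, making the single-guide case an exact
identity.

**Ranking and scores.** Genes are ranked by p-value with ties broken
by gene id; the reported score is `−log10(p)` signed by the gene's
mean LFC direction, giving a continuous ranking axis without inventing
effect-size estimates the tests do not produce.

## Evaluation

PR-AUC uses average precision (the step-function integral of the PR
curve); trapezoidal PR interpolation is known to be biased and is not
used. ROC-AUC is the Mann-Whitney statistic with tie correction.
Empirical FDR at a cutoff is the realized null fraction among genes
with estimated FDR ≤ cutoff, and is *undefined* (serialized as `NA`)
when nothing is called, so aggregates drop the point instead of
absorbing a fake 0 or 1. Sweep tables report per-record values plus
mean/sd over replicate simulations.

Binomial thinning replaces each count by `Binomial(count, p)`,
emulating reduced sequencing depth (thinning by `p` then `q` equals
thinning by `pq`). Guide subsampling keeps a uniform random subset of
guides per gene; pairing a target of `g'` guides with thinning
probability chosen so `g' · p` is constant reproduces the
constant-total-depth guides-vs-depth tradeoff.

## Problem sizes used in the shipped checks

The test suite exercises the full 93,500-guide baseline for
calibration checks (count-mean calibration, null uniformity over
18,600 genes, 20 replicate null screens for FDR behaviour) and a
reduced library of 100 essential / 3,000 null genes with two replicate
simulations per cell for the design-trend sweeps (guides per gene,
guide efficiency, effect multiplier); these sizes keep the whole suite
under a minute on one core while leaving the Monte-Carlo error well
below the effect sizes being asserted. `scripts/acceptance.py`
recomputes the depth calibration on one full baseline screen and the
abundance calibration on 10⁵ draws.

## What the simulation does and does not emulate

It emulates: overdispersed counts with guide-specific representation
effects shared across samples, truncated heavy-tailed gene effects,
per-guide effect variability, Bernoulli guide efficiency, and
sequencing-depth sampling. It does not emulate: copy-number-driven
cutting toxicity, population bottlenecks or growth dynamics,
off-target effects, batch effects, or positive-selection screens as a
distinct mode. Passing benchmarks here therefore speak to a method's
statistical behaviour under calibrated count noise with known truth —
not to its robustness against the biological artifacts listed above.

## Known limitations

- **Null LFC tails.** With two replicates per arm, the null guide LFC
  is essentially the log-ratio of two Gamma(2, ·) sums, which has
  heavier-than-normal tails. The pooled t-test's extreme tail is
  consequently inflated (about 2–4× nominal below p = 10⁻⁴ at the
  defaults), so with ~18,600 genes the family-wise behaviour of
  BH at a 0.1 cutoff under a *global* null is worse than nominal even
  though the bulk of the p-value distribution is uniform (KS < 0.02).
  More replicates lighten the tail. Users comparing methods at
  stringent cutoffs should treat the t-test's smallest p-values with
  caution.
- The RSA-style statistic is anti-conservative under the null (see
  above); it is a ranking method first and a p-value second.
- The LFC estimator is unmoderated; at very low depth (≤ 5 reads per
  guide) the pseudocount dominates and all methods degrade together.
- `empirical_fdr` requires truth labels for every called gene; partial
  truth (as in re-analyses of real screens) must be encoded by the
  caller as explicit null labels.
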