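# Methods

## Study design and data model

The package targets matched case–control omics panels: each of *n* pairs
contributes one patient and one demographically matched control, measured
on the same feature set of non-negative concentrations / relative
quantities. Features carry a role — circulating lipid, plasma
inflammatory mediator, or gene-expression inflammatory mediator — from a
catalog; lipid display names in sum-composition or molecular-species
shorthand (e.g. `PC (O-34:3)`, `TG (16:0/18:0/18:1)`) are parsed into
class / carbon / double-bond / ether annotations. Parsing is total:
unrecognizable names become class `unknown` rather than errors, because
lipidomics platforms routinely emit partially identified species.

## Preprocessing

Four steps, in order, per feature:

1. missing and negative cells → 0 (instrument artifacts and
   below-detection readings are indistinguishable at this point);
2. zeros → half the minimum *strictly positive* observed value. This is
   the standard left-censoring surrogate; the minimum must be taken over
   positive values because step 1 has already mapped everything
   problematic to zero, so the "minimum value" would otherwise be 0 and
   imputation would be a no-op. Features with no positive value at all
   are dropped (logged), since no imputation value exists for them;
3. log2 transform;
4. autoscaling to mean 0, SD 1 across **all** samples jointly (patients
   and controls together, before pairing — scale, then subtract). The SD
   uses the sample convention (ddof = 1, as in R's `scale()`); this is a
   per-feature rescaling and has no effect on any correlation computed
   downstream, but it is recorded in the run manifest and switchable
   (`autoscale_ddof`). Zero-variance features are dropped with a logged
   warning rather than raising: in an exploratory pipeline a constant
   column is uninformative, not fatal.

The **fold-change matrix** is then `scaled(patient) − scaled(control)`,
one row per complete pair. Differencing removes any additive pair-level
effect (the matching variables), which is exactly why association
analysis runs on this matrix rather than on raw samples.

## Association: Spearman ρ and the non-rejection rate

Edge weights are Spearman correlations of the fold-change columns
(Pearson on average ranks; ties get average ranks; constant columns get
ρ = 0 with a warning).

Edge *retention* is decided by the non-rejection rate. For a pair
(i, j), each test draws a conditioning order *q* (uniform on
1..`q_max` by default, or fixed), draws *Q* uniformly without
replacement from the remaining features, computes the sample partial
correlation from the inverse of the correlation submatrix on
{i, j} ∪ Q,

    r(i,j|Q) = −W_ij / sqrt(W_ii · W_jj),   W = inverse submatrix,

and applies the Fisher-z test `z = sqrt(n − q − 3)·atanh(r)` at
two-sided level α: non-rejection iff |z| ≤ z₁₋α/₂. The NRR is the
fraction of non-rejections over `n_tests` draws. Under the null of no
direct dependence the NRR concentrates near 1 − α; a genuine direct
association drives it toward 0. Pairs with NRR ≤ `nrr_threshold` are
kept.

Defaults and rationale:

* `alpha = 0.05` — conventional test level; the NRR histogram, not α,
  carries the retention decision.
* `n_tests = 100` per pair — Monte-Carlo SE of an NRR near 0.1 is
  ≈ 0.03, small relative to the 0.1 retention threshold.
* `q_policy = uniform over 1..q_max`, `q_max = min(p − 2, n − 4, 20)` —
  mixing orders makes retention robust to the choice of a single q; the
  n − 4 cap keeps the Fisher degrees of freedom n − q − 3 positive, and
  20 bounds cost at panel sizes where p ≫ n.
* `nrr_threshold = 0.1` (inclusive ≤) and `rho_threshold = 0.5`
  (inclusive ≥) — the conservative conventions for "non-spurious" and
  "consistent across pairs" at a few dozen pairs; both are required
  config values with these defaults, and no automatic threshold
  selection is attempted (the NRR histogram is emitted precisely so the
  analyst can judge the threshold).

Numerical and reproducibility choices: the feature correlation matrix is
computed once and every test inverts only a (q+2)×(q+2) submatrix, in
vectorized batches grouped by q. An exactly singular submatrix (e.g. an
affine-copy feature pair, |r| = 1) counts as a rejection, consistent
with z = ∞. Conditioning sets are drawn without replacement within a
test but independently across tests; `exhaustive` mode instead
enumerates *all* subsets of each configured order and is the exact
average the Monte-Carlo mode estimates — it is the oracle the test suite
compares against. Each unordered pair gets its own RNG substream keyed
by (seed, sorted indices), so results are independent of evaluation
order and bit-reproducible.

The NRR is computed with Pearson-type covariance on the fold-change
values while reported edge weights are Spearman ρ — filtering and
weighting are deliberately separate statistics.

## Network and candidates

Retained edges are classified by endpoint roles; lipid–lipid edges are
pruned so the graph stays centred on the inflammatory mediators.
Mediator–mediator edges survive pruning (the inflammasome core is part
of the picture) but the default candidate table reports mediator–lipid
pairs only, with a flag to include both. The graph carries role and
lipid-class node attributes and signed, |ρ|-weighted edges; layout is
left to viewers. Candidate records attach the lipid's patient-vs-control
p-value when group tests were run.

## Group statistics

Per-feature patient-vs-control differences use one-way ANOVA + Tukey
HSD. For two groups the studentized range satisfies q = √2·|t|, so the
implementation uses the exact pooled-t identity (k = 2) and the
studentized-range distribution for k ≥ 3. Tests default to the log2
scale (variance-stabilized); concentration scale is available, and the
candidate/group reports carry means on the tested scale. The pairing is
not modelled in this test (plain two-group ANOVA), by design.

The medication confounder scan fits an ordinary Gaussian linear model of
each processed feature on the binary antipsychotic flag, within the
patient stratum by default (controls are unmedicated by design; an
all-samples option exists). For a binary predictor this coincides with
the two-sample t-test. Benjamini–Hochberg and Bonferroni adjusted
p-values are always reported side by side; the pipeline runs the scan on
both log2 and concentration scales.

## Synthetic cohorts and what they do (not) show

The generator builds a sparse precision matrix over
`n_lipids + n_mediators` features: a clique of positive partial
correlations (default strength ≈ 0.18, which inside a 6-clique implies
pairwise marginal correlations around 0.6 — a tightly positively
interconnected core) among the first `core_size` gene mediators, plus
`n_planted_cross_edges` mediator–lipid edges with magnitudes drawn
U(0.5, 0.75) and negative sign with probability 0.73, spread round-robin
over non-core mediators and distinct lipids so the planted marginal
correlations are not distorted by hub effects. If the requested pattern
is not positive-definite, off-diagonals are shrunk 5% per round (at most
200 rounds, then an error); the implied covariance is rescaled to unit
diagonal, which preserves all partial and marginal correlations.

Cohorts are drawn as: shared per-pair, per-feature latent shift (SD 0.5
— the matching effect), plus independent multivariate normal draws with
the implied covariance; patients additionally receive per-feature mean
shifts (defaults: ±0.9 SD on three designated lipids). Latents are
exponentiated base 2 around per-feature baselines, so the log2
preprocessing step recovers the latent Gaussian scale exactly and the
precision matrix remains the meaningful ground truth after
preprocessing. Per feature, the lowest 5% of values (the default
detection-limit quantile) is censored to missing; 18/39 of patients are
flagged as antipsychotic-treated, mirroring a realistic treatment rate.

What passing tests on these cohorts shows: the chain recovers planted
conditional-dependence structure at realistic dimensions, is calibrated
under the null, and is deterministic. What it does not show: robustness
to batch effects, non-lognormal marginals, heteroscedastic measurement
error, feature-correlated censoring, or imperfect matching — none of
which the generator emulates.

## Validation problem sizes

The test suite and the acceptance script validate at deliberately modest
sizes chosen to make the properties sharp: exhaustive-vs-brute-force
agreement at p = 8, n = 40, q ∈ {1, 2}; null calibration at n = 60,
p = 12 over 528 pairs; planted-structure recovery at the study's own
scale (39 pairs, 100 lipids + 20 mediators, 10 planted edges, 10 seeds;
recovery is scored against planted edges whose population Spearman
correlation is at least 0.5, which on the latent Pearson scale means
strengths of 0.55 and up); determinism on a 12-pair, 26-feature cohort.

## Known limitations

* The NRR test uses the Fisher-z normal approximation, slightly
  conservative at very small n − q − 3; the t-form would be
  monotone-equivalent at these sizes.
* Candidate extraction inherits the hard |ρ| ≥ 0.5 cutoff: edges whose
  population correlation sits exactly at the cutoff are found only about
  half the time at n = 39, which is a property of the rule, not the
  implementation.
* The group test ignores the pairing (by design, matching the plain
  ANOVA/Tukey convention), costing some power relative to a paired test.
* No graphical-model estimation beyond the single NRR threshold — no
  graph-order selection, no averaging across NRR variants.
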