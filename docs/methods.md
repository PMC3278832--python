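# Methods

## Model and statistics

A quantitative genetic interaction between genes A and B is the deviation
of the double-mutant fitness from the multiplicative expectation,
ε = φ_AB − φ_A·φ_B, with φ values relative to wild type. Only the sign
and magnitude of ε (plus its reported p-value) enter the statistics; the
package never recomputes ε from raw colony sizes. ε = 0 carries no sign
and is dropped at ingestion, as every statistic below requires a binary
sign.

**Clusters.** A *within-complex* cluster collects the interactions whose
two genes both belong to one complex; a *between-complex* cluster collects
the interactions linking one specific unordered pair of distinct
complexes. Complex catalogs overlap, so one interaction may appear in
several clusters; an optional `exclude_within` flag removes interactions
internal to any complex from all between clusters (off by default).
Clusters with fewer than `min_interactions` (default 2) are discarded
before population statistics.

**β and MCI.** For a cluster with N⁺ positive and N⁻ negative
interactions, β = (N⁺ − N⁻)/(N⁺ + N⁻). The monochromatic index of a
cluster population is

    MCI = Σᵢ Nᵢ |βᵢ| / Σᵢ Nᵢ  ∈ [0, 1],

the interaction-count-weighted mean of |β|: clusters with more screened
interactions are treated as more reliable evidence. MCI = 1 iff every
cluster is sign-pure; MCI = 0 iff every cluster is exactly balanced.
Absolute values are forced by that stated range — a signed mean could not
reach 1 for a population of pure-negative clusters. A cluster is *highly
monochromatic* when |β| strictly exceeds the population MCI.

**sMCI.** The strength-based index replaces the count purity with the
magnitude purity sᵢ = |Σⱼ εⱼ| / Σⱼ |εⱼ| over the cluster's interactions,
aggregated with the same Nᵢ weights. This particular per-cluster form is
a reconstruction: it lies in [0, 1], reduces exactly to |β| when all |ε|
in a cluster are equal (a property the tests verify), and degrades
gracefully as magnitudes vary. Clusters whose ε are all below 1e-12 in
magnitude are rejected rather than scored.

**MP-score.** The per-complex monochromatic purity score adjusts the
cluster's positive fraction f for the background positive fraction f₀:

    MP = (f − f₀)/(1 − f₀)  if f ≥ f₀,   (f − f₀)/f₀  otherwise,

giving +1 for an all-positive complex, −1 for all-negative, 0 at the
background ratio, and monotone behavior in f. This algebraic form is also
a reconstruction — the originally published equation is not recoverable
from available text — so it is isolated behind the single function
`mp_score` where an alternative can be swapped in, and no claim is made
that it matches the original numerically away from the contract points.
A complex is classified monochromatic when |MP| > 0.5, strictly; both
this threshold and the |β| > MCI rule use strict inequalities. With a
degenerate background (f₀ ∈ {0, 1}) the score is defined only for pure
clusters.

**Binomial trend test.** Under the null that each complex is
monochromatic with probability ½, the monochromatic count in n complexes
is Bin(n, ½); significance is the upper tail P(X ≥ x), computed with
exact integer combinatorics (`math.comb` sums divided by 2ⁿ), so even
tails like 0.5⁴⁶ ≈ 1.4e-14 are exact to machine precision.

**Permutation null.** The null for MCI/sMCI redraws each cluster's
contents from the pool of all interactions passing the active cutoff,
keeping the cluster-size multiset fixed. The default draw is joint and
without replacement across all clusters (a true relabeling of pool
interactions); independent per-cluster draws and with-replacement
sampling are available behind flags, since the original procedure's
sampling mode is not documented. Whether never-screened pairs belong in
the pool is unknowable; they carry no sign and are excluded. The
empirical p is the proportion of null values ≥ observed (ties count
against significance; a (r+1)/(b+1) estimator is available), displayed as
`< 1/b` when no replicate reaches the observed value. The z-score is
(observed − μ)/s with s the replicate standard deviation (ddof = 1); a
zero-variance null yields z = NaN, flagged rather than raised. Default
b = 1000 replicates. Given a seed the whole distribution is
bit-reproducible.

## Pipeline conventions

- Cutoffs: lenient p < 0.05; intermediate p < 0.05 and |ε| > 0.08;
  stringent (ε > 0.16 or ε < −0.12) and p < 0.05. Stringent-kept rows are
  a subset of intermediate-kept, which are a subset of lenient-kept.
- Gene identifiers are trimmed and upper-cased before matching; mixed
  case is common across yeast resources.
- Screens test pairs in both query/array orientations;
  `collapse_duplicates` merges concordant-sign duplicates (mean ε, min p)
  and removes discordant-sign pairs entirely — a symmetric, conservative
  policy for records the underlying screen effectively contradicts
  itself on.
- The retention threshold of 2 interactions per cluster is configurable;
  one published description says "more than two" where the procedure
  section says "at least two", and this package follows the procedure
  section's ≥ 2.
- A complex belongs to a cellular subsystem iff *all* its member genes are
  in the subsystem's gene list (flat lists are inputs; ontology traversal
  is out of scope). Subsystems retaining fewer than 2 eligible clusters
  are skipped with a logged reason, mirroring how sparsely screened
  subsystems (e.g. signaling) are excluded in practice.
- Reports derive percentages on the fly and never store them; re-running
  with the same config and seed reproduces the summary byte-for-byte.
  Per-section permutation seeds are derived deterministically from the
  config seed.

## Synthetic-data generator

The generator emulates an SGA-style screen at desk scale: 30 disjoint
complexes of 3–8 genes (uniform); each intra-complex pair interacts with
probability 0.6 and each inter-complex pair with probability 0.1, giving
on the order of 1,500 interactions — large enough for stable cluster
statistics, small enough that the full test suite runs in seconds. Each
cluster (complex or complex pair) gets a planted majority sign; each of
its interactions takes that sign with probability `purity` (default 0.9).
Majority signs are positive with probability
q = (f_positive − (1 − purity))/(2·purity − 1), clamped to [0, 1], so the
marginal positive fraction matches `f_positive` (default 0.35, a
negative-leaning background as real lenient-cutoff screens show); at
purity 0.5 the marginal is 0.5 regardless of q, so f_positive is only
honored where feasible. |ε| is lognormal with median `epsilon_location`
(0.1) and log-sd `epsilon_scale` (0.6); p-values are a mixture of
Uniform(0, 0.05) with weight 0.9 ("significant") and Uniform(0, 1) noise,
so all three cutoffs are exercised.

What the generator does *not* emulate: overlapping complex membership,
gene-specific interaction propensities (hub genes), correlated ε across a
cluster, missing/untested pairs, and the marginal ε distribution of any
real screen. Passing tests therefore demonstrate correctness of the
statistics and their null machinery, not biological conclusions about
real data.

`expected_mci` is the independent parameter-recovery oracle: it
re-simulates cluster sizes, sign draws and lenient-cutoff thinning (keep
probability w + (1 − w)·0.05) directly, without the pipeline code, and
returns the mean, its standard error, and the across-replicate
(dataset-level) standard deviation. A single pipeline MCI is itself one
Monte-Carlo draw of a dataset-level statistic, so recovery is judged
against 3·sqrt(sd² + se²), not 3·se alone, which would reject a correct
implementation with near certainty.

## Numerical choices and limitations

- Binomial tails use exact integers; no log-space approximation is
  needed at the n ≤ a-few-hundred scale of complex censuses.
- β and MCI are exact rational arithmetic in floating point; the
  brute-force oracle equivalence tests assert agreement to 1e-12.
- MP-score at the contract points (f ∈ {0, 1}, f = f₀) is computed
  exactly, with pure clusters short-circuited before any division.
- The piecewise MP reconstruction is discontinuity-free but its slope
  ratio changes at f = f₀; under an extreme background a near-balanced
  complex (e.g. 5:6 vs 6:5) can land on opposite sides of the
  monochromatic threshold — the very instability that motivates MCI, and
  one reason the reconstruction is not claimed to reproduce historical
  MP values beyond its contract.
- Problem sizes used by the test-suite and the acceptance script —
  default generator scale, b = 1000 permutations, 200–300 oracle
  replicates — were chosen as the package's desk-scale study conditions;
  all statistics scale linearly in pool size × b.
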