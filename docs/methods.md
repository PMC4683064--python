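# Methods

## Model

The target study supplies a two-sided P value per SNP; equivalently a Z
score Z_i ~ N(μ_i, 1), where μ_i is the standardized association with the
target phenotype at the study's sample size. Prior knowledge from proxy
studies supplies an estimate η_i of |μ_i| with uncertainty σ:
μ_i ~ N(η_i, σ²), hence marginally Z_i ~ N(η_i, 1 + σ²). The pipeline
treats η as a magnitude throughout — effect directions are unavailable in
several published proxy meta-analyses, and combining magnitudes avoids
sign-convention bugs; directions re-enter only in the overlap and
replication stages, where both studies' directions are known and are
harmonized by allele alignment.

### The prior (cross-trait combination)

Per SNP, two-sided P values across the k proxy studies carrying it are
combined with Fisher's method, F = −2 Σ ln p_i ~ χ² with 2k df. The
meta-P maps to a nonnegative Z via η = max(0, Φ̄⁻¹(p_meta)): quantiles
below zero (meta-P > 0.5) are truncated rather than allowed to penalize a
SNP below genome average, because the prior mean is a magnitude. η is
then scaled to the target sample size as √(N_target/N_proxy)·η. The
square-root convention follows the usual N^{1/2} growth of GWAS
noncentrality; a `convention="linear"` switch exists for sensitivity
analysis but is not the default. Combination happens first (on P values),
then a single scaling is applied with a caller-supplied effective proxy
N. SNPs absent from every proxy study get η = 0 (weight-neutral), so the
full target panel remains weightable; df adapts to per-SNP availability
(2·k_present).

### Optimal weights

Weights w ≥ 0 with mean(w) = 1 turn the per-test one-sided level into
q·w_i; the expected rejection count is E R(w) = Σ Φ̄((t_i − η_i)/γ) with
t_i = Φ̄⁻¹(q·w_i) and γ² = 1 + σ². Each summand is concave in w_i on the
relevant branch, so the equal-marginal (KKT) condition is sufficient:
with multiplier λ for the mean constraint, stationarity reduces to

    (σ²/2γ²)·t_i² + (η_i/γ²)·t_i − η_i²/(2γ²) = ln(λγ).

The *larger* root is taken: it lies on the concave branch
(t > −η_i/σ²) and is the one that degenerates to the point-prior
(Spjøtvoll) solution t_i = η_i/2 + ln(λ)/η_i as σ → 0 (verified
numerically across η ∈ [0, 6] at σ ∈ {0.01, 0.25, 1}). λ is found by
bisection on mean(w(λ)) = 1 (tolerance 1e−10, ≤ 200 iterations, bracket
by doubling); a final renormalization pins the mean at 1 to machine
precision. When the quadratic has no real root (only possible for
λγ < 1), the marginal power exceeds λq at every weight and the
coordinate sits at the cap.

Numerical choices and edge cases:

- **Cap.** q·w_i is capped at 1 (Φ̄⁻¹ is undefined past 1). Capped
  coordinates stay at the cap while bisection continues on the rest.
- **Constant η.** Symmetry plus the mean constraint force w = 1 exactly;
  this is short-circuited so weighted and unweighted analyses are then
  bit-identical.
- **σ = 0** delegates to the Spjøtvoll solver, where η = 0 coordinates
  have constant marginal q: they sit at 0 for λ > 1, at the cap for
  λ < 1, and share the residual mass when the multiplier lands exactly
  on the λ = 1 discontinuity.
- **Extreme η.** All tail computations use scipy's `sf`/`isf`; η up to
  ~40 (post-scaling) keeps every quantity finite.

**Non-monotonicity.** The optimal weight profile is *unimodal* in η, not
monotone: it peaks near η\* = √(2 ln(λγ)) and decreases for stronger
priors. The reason is economic — a SNP with a very large prior mean is
rejected at almost any per-test level, so the marginal power gain of
giving it more budget is small, and the optimizer moves that mass to
borderline SNPs. Ties in η always receive identical weights, and the
unit tests assert the profile's continuity and its agreement with a
multi-start constrained numerical optimizer; a monotone-in-η weight rule
would be strictly suboptimal for the stated objective.

### FDR control

Weighted P values P_i/w_i (clipped to 1; w = 0 ⇒ weighted P = 1) pass
through Benjamini–Hochberg step-up, delegated to
`statsmodels.stats.multitest`. With nonnegative mean-1 weights and
independent P values, BH on weighted P values controls the FDR at the
nominal level regardless of how the weights were chosen — the
optimization affects power only. Discovery uses FDR < 10% by default;
lead SNPs are chosen per caller-supplied LD block as the record with the
lowest adjusted P (ties: smaller weighted P, then lexicographic id).

For small follow-up panels the Benjamini–Liu (1999) step-down procedure
is implemented directly (no installed package provides it): critical
values δ_i = 1 − (1 − min(1, m·q/(m−i+1)))^{1/(m−i+1)} at sorted rank i,
sequential rejection stopping at the first failure. Adjusted values
invert the sequential rule, q_i* = max_{j≤i} (m−j+1)/m·(1−(1−p_(j))^{m−j+1}),
so that "adjusted ≤ q ⇔ rejected at level q" holds exactly (property-
tested). Replication uses this at FDR 5%.

### Overlap enrichment

The shared SNP panel is ranked by target P (ties broken by id for
determinism) and greedily pruned: keep the head, drop all later SNPs
with r² > 0.2 to it, repeat. The threshold is strict — r² exactly at the
boundary is retained. An index SNP already known genome-wide significant
(e.g. the *APOE* region in a longevity scan) can be excluded together
with its r² > 0.2 neighbourhood before the scan, since it would
otherwise dominate the top of the list without being a new finding.
One-sided conversion uses the proxy study's direction; when a proxy
study lacks directions, the two-sided target P is used for both the
top-K list and the background, keeping both sides of the comparison on
the same sidedness. Enrichment is the inclusive upper tail
P[X ≥ observed] of Hypergeometric(n_background, background_hits, K) —
enrichment is a one-sided question. QQ coordinates use plotting
positions i/(n+1), the mean of the i-th uniform order statistic.

### Replication

Per cohort, the two-sided P becomes p/2 when the cohort's effect
direction for the protective allele matches discovery and 1 − p/2 when
it opposes (alleles aligned first; allele-swapped records are flipped).
Missing SNPs may be substituted by an explicit caller-supplied proxy,
validated against the LD table when available (r² > 0.8 and D′ = 1; an
absent D′ is not held against the proxy). There is no automatic proxy
search — that requires external reference panels. Cohort one-sided P
values are combined with unweighted Stouffer, 1 − Φ(Σ Φ⁻¹(1−p_i)/√k),
over exactly the cohorts where the SNP was testable; SNPs testable
nowhere are flagged rather than dropped silently. When a discovery
direction is unknown the cohort's two-sided P is used with a warning.

## Synthetic data

The generator works at the Z-score level — the toolchain consumes
summary statistics, so genotype simulation would add realism the methods
never see. Per study, Z_i = μ_i + √ρ·F_b + √(1−ρ)·ε_i with one standard
normal factor F_b per LD block and ρ = √(block r²), giving every
same-block pair a squared correlation equal to the nominal block r².
Defaults (chosen once as a realistic desk-scale configuration): 10,000
SNPs in 500 blocks of 20, block r² = 0.5, 1% shared-causal SNPs and 1%
proxy-only causal SNPs, causal effects N(5, 1) in units of target-study
noncentrality, target N = 2,000 and proxy N = 30,000 (the 15× midpoint
of the 10–20× size ratio typical of disease meta-analyses relative to
longevity cohorts). Shared-causal SNPs carry a common latent effect with
the target-study sign flipped (disease risk alleles depleted in the
long-lived group); the proxy noncentrality is scaled by √(N_proxy/N_target).
A seed is mandatory; identical spec ⇒ bit-identical output.

What the generator does *not* emulate: allele-frequency-dependent power,
realistic LD decay (blocks are exchangeable within and independent
between), population stratification, overlapping samples between proxy
and target, and correlated proxy traits. Passing tests therefore show
that the machinery is correct under its own model — independence between
blocks, Gaussian effects, honest priors — not that real-data violations
of those assumptions are harmless. In particular, BH's FDR guarantee
under the generator's independent-null configuration says nothing about
LD-induced dependence in a real scan, where lead-SNP selection per block
is the mitigation.

The `power_fdr_experiment` harness runs the full pipeline (prior →
weights at q = 1/S → weighted and unweighted BH at the chosen FDR level)
per replicate and reports mean true discoveries and empirical FDR with
Monte-Carlo standard errors. At the default sizes a replicate costs
~0.1 s, so the standard experiment sizes (500 null replicates; 200
informative replicates) complete in a couple of minutes on one CPU.

## Known limitations

- Strand harmonization is not attempted: A/T and C/G SNPs pass through
  unchanged, and allele mismatches beyond a swap exclude the record with
  a logged count. Sources must be on a common strand.
- The weighting assumes the prior η is independent of the target P
  values (different cohorts). Overlapping samples would both bias the
  prior and void the FDR argument.
- Redundant proxy traits are a configuration concern: the caller chooses
  which studies enter the Fisher combination; no correlation adjustment
  (e.g. Brown's method) is applied.
- Positions are carried but never used; LD tables are authoritative for
  linkage. There is no liftover and no genotype-file parsing.
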