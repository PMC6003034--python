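# Methods

## Scope and data model

The package analyses tables of oil samples.  Each sample carries
categorical metadata (cultivation region, extraction procedure), a
fatty-acid profile in percent of total FAME peak area, and optionally the
raw readings behind its quality indices.  Seven published argan oils —
Tunisia (solvent), Morocco (cold-pressed cosmetic, solvent, cold-pressed
edible) and Algeria (Tindouf solvent, Tindouf cold-pressed, Mostaganem
solvent) — are embedded in `arganet.datasets` and serve as the reference
dataset throughout.

## Quality indices

All five content formulas are linear (homogeneous of degree one) in the
driving reading:

| quantity | formula | units |
|---|---|---|
| free acidity | V·C·M / (10·m) | % oleic acid |
| acid index | V·56.1·N / m | mg KOH / g |
| polyphenols | 403.68 · A₇₂₅ | ppm |
| chlorophyll | [A₆₇₀ − (A₆₃₀+A₇₁₀)/2] / (0.1086·L) | ppm |
| carotenoids | A₄₇₀·25·10⁴ / (2000·7.5) | ppm |

The oleic molar mass defaults to M = 282.46 g/mol and is configurable.
The polyphenol multiplier 403.68 is treated as a fixed protocol constant
for the 10 g oil extraction (its calibration curve is not part of the
package).  A noisy spectral baseline can make the chlorophyll numerator
negative; since a pigment content cannot be negative the value is floored
at 0 and a warning is logged.  Linearity makes all formulas exactly
invertible, which the synthetic module exploits to generate fixtures
whose round-trip error is at machine precision (~1e-15, tested at 1e-9).

Quality grades are configuration, not chemistry: the default bands
[0, 0.2) → refined, [0.2, 1.0] → extra virgin, (1.0, 2.0] → virgin,
(2.0, ∞) → lampante reproduce all six reference labels.  The
non-monotonicity (very low acidity ⇒ refined) is deliberate: refining
strips free fatty acids below what fresh virgin oil shows, so an acidity
of 0.11–0.12 % indicates a refined oil rather than an exceptional virgin
one.  Band lists are validated for gap-free, overlap-free coverage of
[0, ∞).

## Derived nutritional indices

With the four-acid profile (palmitic P, stearic St, oleic O, linoleic L):
SFA = P + St, UFA = O + L, P/S = L / SFA, UFA/SFA = UFA / SFA.  Linoleic
is the only polyunsaturated acid in the four-acid profile, hence the P/S
numerator.  Internal arithmetic keeps full precision; two-decimal
rounding happens only in reports.  Recomputed indices agree with every
published cell within one unit of the last printed decimal; the single
cell that does not round identically (Tindouf-solvent P/S: 28.99/19.52 =
1.4851 vs printed 1.48) is consistent with the authors having rounded
from unpublished full-precision measurements.

Compositions are compositional: profiles must close to 100 % within a
tolerance (default ±1.0 %).  Three of the published columns sum to
98.3–98.8 % because minor acids were left untabulated, so the embedded
dataset loads with an explicit ±2.0 % tolerance.

## Correlation screening

Pearson r with exact two-sided p-values from the t transform with n−2
degrees of freedom.  Categorical variables enter as integer codes
(defaults: Tunisia=1, Morocco=2, Algeria=3; solvent=1, mechanical=2,
cold/hand pressing=3); any correlation involving them is
coding-dependent and results carry their encoding.  Zero-variance
columns are excluded with a warning.  No multiple-testing correction is
applied by default, matching the raw p < 0.05 convention of small
comparative oil studies; a Benjamini–Hochberg option exists.

A reproducibility caveat established while validating against the
published study: the oleic-vs-P/S entry (r = −0.946, p = 0.001) is
reproduced exactly when the P/S column is taken as printed (two
decimals); recomputing P/S at full precision shifts r to −0.945.  Other
published entries (palmitic–oleic 0.944, linoleic–P/S 0.987) cannot be
reproduced from the printed composition at all (recomputation gives
≈0.872 and ≈0.982) and evidently rest on unpublished replicate
measurements; the package does not assert them.

## The partial-correlation network

**Model.** Encoded variables are treated as jointly Gaussian; edges of
the network are conditional dependencies, i.e. nonzero entries of the
precision matrix Ω.

**Shrinkage.** The reference regime has n = 7 < p = 10, so the sample
correlation matrix S is singular.  On the standardized scale
(columns centered, unit sd with denominator n−1) the covariance is
shrunk toward the identity, Σ(λ) = (1−λ)S + λI, with the analytic
intensity

λ\* = Σ_{i≠j} Var̂(r_ij) / Σ_{i≠j} r_ij²,  clipped to [0, 1],

where Var̂(r_ij) = n/(n−1)³ · Σ_k (z_ki z_kj − mean_k)².  Uncertain
correlations (large Var̂) push λ up; strong, precisely estimated
correlations push it down.  For truly independent columns λ\* → 1 at any
n — correctly, since the identity is then the truth.  Ω = Σ(λ)⁻¹ is
symmetric positive definite for any λ > 0.  λ = 0 reproduces the
classical unshrunk estimate (valid when n > p) and is verified against
an independent residual-regression oracle: for every pair, the partial
correlation equals the correlation of OLS residuals after regressing
both variables on all others (agreement to 1e-10).

**Skeleton.** ρᵢⱼ = −ωᵢⱼ/√(ωᵢᵢωⱼⱼ); pairs with |ρᵢⱼ| ≥ τ are joined.
τ is not identifiable from the reference study and defaults to 0.3,
configurable.  An |ρ| threshold rather than a significance test keeps
the construction transparent at desk scale.

**Orientation.** Each node's score is its standardized partial variance
gₖ = σₖₖ/ωₖₖ (σₖₖ = 1 after standardization), the share of the node's
variance unexplained by all others.  An edge (i, j) is oriented i → j
when Bᵢⱼ = gᵢ/gⱼ > 1, j → i when < 1, and left undirected within a tie
tolerance (default 1e-9; exact floating-point ties essentially never
occur, so the tolerance honors the theoretical B = 1 case).  Because all
edges follow one total preorder, **the directed graph is acyclic by
construction** — asserted on every build and fuzz-tested.  Bᵢⱼ·Bⱼᵢ = 1
identically.  Standardization before orientation is mandatory in the
default path because the raw-scale reading of the B formula and the
partial-variance ordering disagree off the standardized scale; a
`standardize_data=False` switch exposes the literal raw-scale reading
for completeness.

**What the heuristic can and cannot do.** On a causal chain
x₀ → x₁ → x₂ with unit noises, the population scores are
g = (1/(1+β²), 1/(1+β²)², 1/(1+β²+β⁴)): the root is the least-explained
node, so its arc correctly orients x₀ → x₁, but the middle node is the
*best*-explained one, so the downstream edge orients x₂ → x₁.  On a fork
the root is explained by all its children and receives incoming arcs.
The orientation is therefore an exogeneity ordering, not consistent
causal discovery — the tests assert exactly what the mathematics
guarantees (root arc on chains, acyclicity, reciprocity) and skeleton
recovery (≥ 80 % of true edges at β ≥ 0.7, n = 500, τ = 0.2) rather than
full orientation recovery.

**Reference dataset under defaults.** At n = 7, p = 10 the analytic
λ ≈ 0.39 compresses every partial correlation below 0.23, so the default
network over the ten study variables has no edges.  That is the honest
output of the stated procedure: seven samples cannot support a
ten-variable conditional-dependence graph.  The graph published for this
dataset is not reproducible without the original authors' categorical
coding, threshold and replicate data; users exploring it can lower τ or
λ and will still obtain a DAG.

As λ → 1 all partial correlations vanish; the *maximum* |ρᵢⱼ| decays
monotonically in λ, but individual near-zero pairs may wiggle through
sign changes on the way, so only the aggregate monotonicity is asserted.

## Synthetic data

* `simulate_sem` draws from linear-Gaussian SEMs (node = Σβ·parent +
  N(0, sd), topological order, explicit seed).  The implied covariance
  (I−B)⁻ᵀD(I−B)⁻¹ is available in closed form for convergence checks;
  the one-edge model with β = 1 has corr = 1/√2, verified within ±0.05
  at n = 2000 across 20 seeds.
* `simulate_oil_table` adds Gaussian noise to group-mean profiles and
  re-closes each sample to 100 % (noise then renormalization, because
  compositions are closed; negative draws are resampled with bounded
  retries).  The default cohort is 3 regions × 2 extraction procedures ×
  5 replicates (n = 30 > p, so unshrunk paths stay testable), with group
  means spanning the composition range reported for argan oils.
* `absorbance_fixtures` inverts the quality formulas exactly (the
  chlorophyll baseline at 630/710 nm is drawn at random, seeded, and
  A₆₇₀ placed to hit the target).

What the generators do **not** emulate: chromatographic peak overlap and
identification errors, non-Gaussian measurement noise, inter-laboratory
protocol differences, and the closure-induced negative correlation bias
of real compositional data beyond the renormalization step.  Green tests
therefore certify the arithmetic and the statistical machinery, not the
field performance of the heuristic on real cohorts.

## Numerical choices

* Correlations are clipped to [−1, 1] before the t transform; |r| = 1
  maps to p = 0.
* Ω is symmetrized after inversion to cancel round-off.
* Zero-variance detection uses a relative threshold
  (sd ≤ 1e-12 · max(1, |mean|)) since a constant float column has
  sd ≈ machine-eps · |mean| rather than exactly 0.
* Problem sizes in the test-suite simulations (n = 500 per SEM
  replicate, 100 replicates; 1000 random network builds) were chosen as
  the smallest sizes at which the asserted population properties are
  stable across seeds.
* Presentation rounding: 2 decimals for percentages/indices, 3 for r, p,
  ρ and B.

## Known limitations

* The orientation heuristic's arcs encode an exogeneity ordering; they
  must not be read as causal effects (see above).
* Correlations with region/extraction depend on the integer coding of
  those labels; alternative codings are configuration, and reports
  always carry the coding used.
* Grade bands are calibrated to one comparative study's labels, not to a
  regulatory standard; users should supply jurisdiction-specific bands
  for compliance work.
* The embedded reference compositions omit minor fatty acids (columns
  close only to ~98–100 %), so SFA/UFA totals are lower bounds for those
  oils.
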