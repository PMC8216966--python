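# Methods

This note documents the models and procedures implemented in `feediv`,
the parameters that matter, the numerical conventions, and what the
package's synthetic data do and do not establish about real data.

## Trait space and normalization

A species pool of *N* species with *M* continuous traits defines the
analysis frame. Each trait is min–max normalized over the pool,
`x′ = (x − min)/(max − min)`, placing all species in the unit
hypercube `[0, 1]^M`. Two consequences drive the design:

* **Bounds always come from the pool, never from a community.** All
  communities in an analysis share one frame; a community is rejected
  if it names a species outside the pool, because a coordinate outside
  `[0, 1]` would leave the support of the null model.
* **A constant trait column maps to zero** (with a warning) rather than
  raising: the species genuinely coincide in that dimension, and the
  MST handles zero-length branches without special cases.

Dissimilarity is Euclidean distance in the normalized space; in an
*M*-dimensional hypercube no distance exceeds `√M`. Only continuous
traits are supported — Gower distances and ordination preprocessing for
mixed trait types are out of scope.

## The FEE₀ statistic

For a community of richness *n* ≥ 2 the minimum spanning tree of its
points has branch lengths `l₁ … l₍ₙ₋₁₎` with mean `l̄`, and

    FEE₀ = Σᵢ min(lᵢ, l̄) = Σl · Σᵢ min(lᵢ/Σl, 1/(n−1)).

FEE₀ is bounded by the total MST length, with equality exactly for
equal branches; the second factor (in `(0, 1]`) is the branch-evenness
component. Conventions at degenerate inputs: coincident species
contribute zero-length branches as ordinary values; an all-coincident
community has FEE₀ = 0, and its evenness component is defined as 1
(the equal-branch limit — inert, since FEE₀ is 0 regardless).

The MST is computed with a dense-matrix Prim's algorithm, vectorized
over candidate edges. Ties are broken deterministically by first
minimum in index order; tied distance matrices can admit several MSTs
with different branch multisets, but the total length — and therefore
any quantity the tests freeze — is unaffected. Branch lengths are
reported sorted ascending. The implementation is verified in the test
suite against exhaustive enumeration of all labeled spanning trees
(Prüfer sequences) for n ≤ 6.

## Null-model standardization

FEE₀ increases with richness, so raw values are never compared across
*n*. Instead, for each (n, M) a null distribution of FEE₀ is built from
*Q* random communities of *n* points (default **Q = 10,000**; the
built-in studies use Q = 2,000, which moves the reported correlations
by less than the Monte-Carlo noise), and

    FEE = #{ FEE₀(null) ≤ FEE₀(observed) } / Q,

the right-continuous empirical CDF with ties counted inclusively and no
interpolation. Two samplers are available: `uniform` (i.i.d. points in
the hypercube — the no-prior-knowledge default) and `pool` (n species
drawn without replacement from the pool's normalized rows, since a
community is a species subset). Null communities are always
equal-abundance; the same curves serve the abundance-adjusted
statistic, whose branch lengths live on the same scale. By the
probability-integral transform, FEE of randomly assembled communities
is uniform on `(0, 1]` at every richness — richness independence is a
construction, not an empirical accident, and the test suite checks it
by Kolmogorov–Smirnov at richness 2–100.

Null curves are cached in a library keyed exactly by (n, M, sampling);
there is deliberately no fallback to a neighbouring richness. One
library seed derives an order-free substream per (n, M), so a library
is reproducible regardless of build order. Persistence is a
gzip-compressed text format with samples serialized as hex floats for
bit-exact round trips; corrupted or truncated files are refused
outright.

## Abundance adjustment

Relative abundances `wᵢ = Aᵢ/ΣA` shrink pairwise distances before the
MST is recomputed:

    dist_a = min(K₁K₂, 1) · dist,
    K₁ = (2/n)/(wᵢ+wⱼ),   K₂ = 2k/(k+1),  k = max(wᵢ,wⱼ)/min(wᵢ,wⱼ).

K₁ < 1 for pairs more abundant than average, K₂ ≥ 1 grows with
within-pair imbalance, and the cap at 1 guarantees `dist_a ≤ dist` —
abundance differences can only contract the occupied trait space
relative to the equal-abundance case, never extend it. Equal abundances
leave every distance unchanged, so presence–absence data (represented
internally as `wᵢ = 1/n`) and the unweighted statistic coincide. Each
pair is adjusted independently; the adjusted matrix may be non-metric,
which is acceptable because the MST needs only a complete symmetric
matrix. A member with zero abundance is dropped (with a warning) before
weighting: the pair-imbalance ratio is undefined at w = 0 and a species
with no individuals is absent.

## Reference indices

FRic (convex-hull volume; trait range for M = 1), FEve (MST-based
partial weighted evenness), FDiv (hull-vertex centre-of-gravity
divergence), FDis (weighted distance to weighted centroid) and Rao's
quadratic entropy follow the conventions of the standard FD/ade4 R
implementations, because the published comparisons this package
reproduces were computed with them. In particular Rao's Q is
`ΣᵢΣⱼ wᵢwⱼ d²ᵢⱼ / 2` — squared half-distances, exactly what `ade4::divc`
computes (verified against it on a fixture) — not the linear-distance
variant; the choice moves the FDis–Rao correlation in the null-model
study from ≈0.945 to ≈0.975. Preconditions (FRic/FDiv need n > M and a
non-degenerate hull, FDiv needs M ≥ 2, FEve needs n ≥ 3) surface as
`UndefinedIndexError` and become recorded missing values in batch
output rather than aborting an analysis — availability differs by
index, and that difference is itself part of the results.

## Lottery assembly simulation

A zero-sum individual-based lottery on a 200-species pool with uniform
1-D traits: 30 founder species × 5 individuals (J = 150), 150
generations; each generation `round(0.02·J)` individuals die (victims
uniform over individuals, i.e. a multivariate hypergeometric draw over
species) and every vacancy is refilled — 80% by local reproduction
(parent species ∝ abundance × recruitment weight) and 20% by
immigration (pool species ∝ recruitment weight). J is conserved
exactly. Vacancies within a generation are refilled as a batch from
weights evaluated on the post-mortality state; with 3 deaths per
generation the difference from sequential refilling is negligible. A
binomial death count is available behind a flag.

The three processes differ only in the recruitment weight:

* **neutral** — 1 for every candidate.
* **niche filtering** — `exp(−(t − t_opt)²/(2σ_env²))`, default
  `t_opt = 0.5`, `σ_env = 0.25` (units of the normalized trait axis).
* **limiting similarity** — a Macarthur–Levins competition load,
  `exp(−Σⱼ exp(−dⱼ²/(2σ_comp²)))` over distances to every *other*
  resident species, default `σ_comp = 0.05`; a candidate with no other
  residents carries no load.

The filter forms and widths are this package's design choices, made
once against three qualitative requirements: the classical diversity
ordering LS > neutral > NF must emerge clearly at a few hundred
replicates; FEE must not saturate at its bounds under either non-neutral
process (a saturating nearest-neighbour LS penalty freezes communities
into near-perfect spacing, pinning FEE at 1 and erasing any
FEE–richness trend); and richer filtered communities should score lower
FEE than sparse ones, as expected when more species share a fixed
filter. The competition-load form satisfies all three; its σ_comp is
deliberately below the typical nearest-neighbour spacing (~1/50) of
simulated communities. Under these dynamics mean richness *rises* from
30 toward ~50 under neutrality, because immigration from the
200-species pool introduces novel species faster than 2%-turnover drift
removes them; limiting similarity holds richness lower (~40) by
suppressing recruitment into crowded trait neighbourhoods.

## The two studies

**Null-model correlation study.** 200 equal-abundance communities at
every richness 2–100, each drawn from its own fresh 300-species uniform
two-trait pool (19,800 communities); all indices per community; full
Pearson matrix with two-sided p-values, undefined values deleted
pairwise with counts reported. An optional richness window restricts
the correlation analysis without regenerating communities (index
relationships are known to be sensitive to the richness range).

**Assembly-detection study.** Per replicate, one pool and one founder
community are shared by all three processes (the pairing structure);
one-sided paired t tests evaluate `neutral > NF` and `LS > neutral` for
each index and mode, and per-process OLS regresses each index on final
richness. Default 300 replicates. Zero-variance paired differences are
reported as degenerate (t = 0, p = 0.5) rather than raising.

Randomness: one master seed spawns independent, order-free substreams
(NumPy `SeedSequence` spawn keys) for pools, communities, null curves
and simulations, so end-to-end reruns are bit-identical.

## What the synthetic data do and do not show

The generators emulate exactly the idealized conditions the index is
defined against: uniform independent traits, random subsets as
communities, lottery dynamics with a single trait. Passing tests
establish the index's internal properties (richness independence,
bounds, orderings, abundance behavior) under those conditions. They do
not establish behavior under correlated or clustered real trait
distributions, mixed trait types, measurement error, or intraspecific
variation; for real pools with strongly non-uniform traits the `pool`
null sampler is the appropriate calibration, and the choice of species
pool itself materially affects the index.

## Known limitations

* Continuous traits and Euclidean distance only.
* Null curves must be built per (n, M); a missing curve is an error by
  design, so batch analyses should pre-build the richness range.
* The empirical CDF has resolution 1/Q; FEE values are exact multiples
  of 1/Q and comparisons finer than that are meaningless.
* Simulation t-statistics depend on the chosen filter forms and widths;
  only orderings, signs and significance are comparable across
  implementations, not point values.
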