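# Methods

`nursepart` analyses how a nurse (cushion) plant's intraspecific genetic
variation, its engineering of soil chemistry, and geography relate to the
composition of soil fungal communities. The pipeline starts from four
processed tables — a MOTU read-count table, sample metadata, soil
chemistry, and a binary AFLP fingerprint matrix for the host plants — and
proceeds through filtering, distance construction, dissimilarity
regression with variance partitioning, and habitat-association testing.
This note records the models, the parameters that matter, and the design
choices made where the procedure was genuinely open.

## Filtering and transforms

Count tables are filtered in a single pass: samples with fewer than 900
total reads are removed first, MOTU totals are then recomputed and MOTUs
with fewer than 10 reads are discarded. Taxonomy-based screening (e.g.
restriction to fungal MOTUs) is expressed as an optional keep-list because
taxonomic assignment happens upstream of this package. The filter is not
re-applied iteratively; in the rare situation where MOTU removal drags a
kept sample back below the read threshold the table is returned as-is
after one pass, matching the order in which the two rules are stated.

Relative abundance divides each sample row by its total; the Hellinger
transform takes square roots of relative abundances, which damps the
influence of dominant MOTUs on Bray–Curtis dissimilarities (their
contribution per unit of abundance change shrinks, while rare-MOTU
contrasts gain weight).

## Distance layers

* **Community**: Bray–Curtis, d(i,j) = Σ|x_ik − x_jk| / Σ(x_ik + x_jk),
  on relative or Hellinger rows (never raw counts, so read depth cannot
  masquerade as turnover).
* **Plant genetic**: Jaccard distance 1 − a/(a+b+c) on binary AFLP rows,
  ignoring shared absences; re-labelled to cushion soil samples through
  the plant-to-sample map. Bare soils host no plant, so genetic predictors
  exist only for cushion-only analyses.
* **Soil chemistry**: Euclidean distance on the six variables (total N,
  total C, gravimetric water, NO3⁻, NH4⁺, pH), each centred and scaled to
  unit variance over exactly the sample set being analysed (a
  cushion-only layer is standardized over cushions alone). For
  cushion-only models a second, bare-soil chemistry layer represents each
  cushion by the mean chemistry of the bare soils at its site; this is the
  package's reading of "chemistry beneath and outside cushions" as two
  separate predictors, since no per-pair bare attachment is defined
  upstream.
* **Geography**: planar Euclidean distance on projected metre
  coordinates. A helper projects lon/lat equirectangularly about the
  centroid; at the ~10 km extent of a typical design the projection error
  is negligible relative to site spacing.

Cognate cushion/bare contrasts pair every cushion sample with every bare
sample of the same site; they quantify abiotic and biotic soil
engineering and feed the per-group rank-sum summaries. Per-sample
diversity uses the inverse Simpson index 1/Σp², the effective number of
equally abundant MOTUs.

## Dissimilarity regression (GDM)

Community dissimilarity d_ij for pairs of samples is regressed on
monotone transforms of predictor distances:

    E[d_ij] = β0 + Σ_k Σ_m β_km I_m(x_k,ij),   β_km ≥ 0.

Each predictor gets three monotone I-spline basis functions of degree 2
(reversed cumulative sums of a quadratic B-spline partition of unity),
with knots at the 0/0.5/1 quantiles of the observed predictor distances.
Non-negative coefficients guarantee a nondecreasing fitted distance-decay
curve for every predictor; basis count and knot quantiles are
configurable. Pairs are treated as independent observations — a known
approximation shared by dissimilarity modelling generally — with n = the
number of pairs wherever a sample size enters.

Two links are available. The default identity link makes the fit a
bound-constrained linear least-squares problem, solved exactly and
deterministically (`scipy.optimize.lsq_linear`, BVLS); exactness matters
because the variance partition relies on nested-model monotonicity at
1e-8 tolerances. The alternative `negexp` link fits the classical
saturating curve E[d] = 1 − exp(−η) by bounded L-BFGS-B from a zero
start.

Explained variance per predictor subset S is Nagelkerke's pseudo-R²
computed from a Gaussian likelihood with the error variance profiled
out. For a continuous likelihood the Cox–Snell ratio
1 − exp(2(ℓ0 − ℓ)/n) attains its maximum of 1 at a perfect fit, so
Nagelkerke's rescaling is the identity and the statistic reduces to
1 − RSS(S)/RSS(∅) — a smooth monotone transform of the residual sum of
squares, guaranteed to lie in [0, 1] for these nested non-negative fits.
(Dividing literally by 1 − exp(2ℓ0/n), as one would for a discrete
likelihood, is ill-defined here: a Gaussian density can exceed 1 and the
denominator can go negative.)

## Variance partitioning

For p ≤ 4 predictors, all 2^p − 1 non-empty subsets are fitted and the
exclusive (Venn-region) values c(T) solve the linear system

    R²(S) = Σ_{T : T ∩ S ≠ ∅} c(T)   for every non-empty S.

Pure fractions are the singleton regions and satisfy
c({i}) = R²(full) − R²(full \ {i}); for two predictors the solution is
the classical commonality pair c({1}) = R({1,2}) − R({2}),
c({1,2}) = R({1}) + R({2}) − R({1,2}). Joint regions can be negative
(suppression) and are reported unclamped. Significance testing of the
fractions is out of scope.

## Habitat association

Samples are grouped into six habitats crossing plant genetic cluster
(x = exscapa, l = longiscapa), bedrock (G = granite, C = limestone) and
location (c = cushion, b = bare); quartzite sites and plants that cannot
be assigned to a cluster (below 80% single-cluster AFLP membership
upstream) are excluded. A MOTU occurs in a sample when its relative
abundance strictly exceeds 0.1% (the boundary itself does not count; the
threshold and the pre-/post-Hellinger table choice are configurable, and
occurrence is always computed on the untransformed relative table by
default). Each MOTU's 2×6 present/absent table is tested with the
chi-square of independence; per-habitat Pearson residuals
(O − E)/√E of the present row measure the direction of association.

P-values come from permuting habitat labels across samples (one shared
permutation stream for all MOTUs, B = 10,000 by default), with
p = (1 + #{χ²_b ≥ χ²_obs})/(1 + B), then Benjamini–Hochberg correction.
A MOTU is flagged plant-associated when the corrected p < 0.05, some
cushion habitat has residual > 2, and no bare habitat does. Note the
joint rule is deliberately two-sided in the residual cut: raising the cut
tightens the cushion requirement but also relaxes the bare exclusion, so
selection is monotone in the cut only while no bare residual sits near
it.

Sample-level permutation assumes exchangeable samples; with spatially or
site-correlated communities it is anticonservative (the synthetic null
experiments below quantify this). A site-level unit (`unit='sites'`)
permutes each site's cluster+bedrock prefix across sites while samples
keep their cushion/bare location, providing the conservative sensitivity
variant.

Taxon-group abundance shifts beneath vs. outside cushions are tested by
likelihood ratio between two mixed models fitted by maximum likelihood —
intercept plus a random site intercept, with and without location as a
fixed effect — with p from χ²(1) and BH correction across groups. If the
mixed fit is degenerate (e.g. zero variance), the test falls back to a
site-stratified permutation of location labels and flags the method.

## Ordinations

Chemistry PCA is an eigen-decomposition of the correlation matrix
(centred, unit-variance variables), with a deterministic sign convention.
NMDS minimizes Kruskal stress-1 by alternating isotonic regression of
configuration distances on the observed dissimilarity order with Guttman
majorization, over 20 random starts (seeded, best final stress kept);
scores are rotated to principal axes. Strongly clustered inputs can reach
near-zero stress through the classical cluster-collapse geometry of
non-metric scaling — a near-zero stress on clustered data should be read
as "the rank order is trivially embeddable", not as a rich configuration.
Environmental vectors are least-squares directions of each variable in
score space with R² the variance fraction explained and permutation
p-values. Rank-sum (two-sided Mann–Whitney) comparisons of cognate-pair
shifts between bedrock×cluster groups use independent pairs by default;
because pairs within a site share samples, a site-mean variant is
provided and is the right choice for inference.

## Synthetic data

The generator emulates the assumed field design: 17 sites (9
granite/exscapa, 5 limestone/exscapa, 3 limestone/longiscapa) on two
massifs 9 km apart so geography partially covaries with bedrock, five
cushion and five bare cores per site, 500 MOTUs at depth 10,000, and 300
AFLP loci. Chemistry is bedrock baselines (e.g. pH 5.0 on granite vs 7.4
on limestone) plus a cushion engineering shift (N, C, water, NH4⁺ up;
pH up on granite only) that is three times stronger for exscapa than for
longiscapa, plus Gaussian measurement noise small enough that the
configured 3:1 contrast is recoverable from cognate-pair distances.
Communities are multinomial draws from a softmax over MOTUs of a
log-normal baseline, a bedrock effect, habitat-signature boosts, a
spatially autocorrelated Gaussian field (exponential covariance, 3 km
range) and iid noise. Ten signature MOTUs are designated per habitat and
kept rare elsewhere by construction; cushion habitats recruit theirs at
full boost with one *dominant* recruit receiving an extra boost (the
dominance that depresses inverse-Simpson diversity beneath cushions),
while bare habitats carry only modestly boosted habitat-specific
background taxa. AFLP fingerprints are Bernoulli draws from two
cluster profiles diverging symmetrically around shared ancestral
frequencies. All generators are pure functions of the configuration
including its mandatory seed.

What the generator does *not* emulate: individual-level plant genotype
effects on communities (the genetic signal is habitat-mediated, so its
*pure* partition fraction on full synthetic data is near zero once
chemistry and geography are in the model — unique genetic effects are
instead exercised by `simulate_gdm_pairs`, which builds the response
directly as d = 1 − exp(−Σ w_k x_k) + noise from known weights);
overdispersion beyond multinomial sampling; unequal site sizes; and
taxonomic structure. Passing recovery tests therefore demonstrate that
the machinery finds structure of the assumed form at realistic sizes, not
that field data contain such structure.

## Numerical choices and problem sizes

Tolerances: partition linear algebra is exact to solver precision and
asserted at 1e-8; two-predictor closed forms at 1e-10; statistic oracles
at 1e-9. Distance matrices must be symmetric to 1e-12 with zero
diagonals. Degenerate cases: all-zero sample rows, constant predictors,
constant chemistry variables, empty fingerprint unions and all-present /
all-absent MOTUs raise informative errors or are flagged rather than
silently handled. Ties at the 0.1% occurrence boundary are excluded
(strict inequality).

Test and verification runs use a scaled-down design (typically 9 sites ×
4–5 samples per location, 150–300 MOTUs, depth 4,000–5,000, 199–999
permutations) chosen so the whole suite completes in minutes while
keeping every habitat populated; the weight-recovery experiment uses the
64-sample, 2,016-pair configuration with 50 replicates.

## Known limitations

Pairwise observations are not independent, so likelihoods and
permutation nulls are approximations; partition fractions carry no
significance tests by design; the identity link can in principle fit
values outside [0,1] at extreme predictor combinations; and the
sample-level permutation null is anticonservative under within-site
correlation (use the site-level unit for a conservative read).
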