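# Methods

`paleotrait` reimplements, as a tested library, a trait-based analysis of
late-Quaternary plant communities recovered from permafrost sedimentary DNA
(sedaDNA). The data model is a sample × MOTU read-count matrix (MOTU =
molecular operational taxonomic unit), per-sample metadata (site,
coordinates, age in ka BP), and a per-MOTU table of five categorical
traits: growth form, mycorrhizal type (AM/ECM/ERM/NM), mycorrhizal status
(OM/FM/NM), N-fixation, and pollination mode. This note documents the
statistical procedures, the choices made where the design was genuinely
open, and what the synthetic-data generator does and does not emulate.

## Period classification and filtering

Samples are binned by age into pre-LGM (> 25 ka BP), LGM (15–25 ka BP) and
post-LGM (≤ 15 ka BP). The interval closure is a package convention —
(25, ∞), (15, 25], [0, 15] — chosen for determinism; ages falling exactly
on a boundary belong to the younger period.

Filtering proceeds rare-MOTU removal first (total reads < 5 by default),
then removal of MOTUs undefined for *any* trait, then removal of samples
left with zero reads. The order is fixed for determinism; on data whose
rare MOTUs were already removed upstream it is immaterial. Trait tables
merged from several literature sources follow a most-recent-first
precedence rule: each MOTU/trait cell takes the first source that defines
it. The NM-type ⇔ NM-status invariant is enforced after merging.

## Trait association

Pairwise trait association is Cramér's V = √(χ²/(n·(min(r,c)−1))) on the
contingency table of defined levels, with the Pearson chi-square computed
without continuity correction (the usual convention for V) and p from the
χ² distribution on (r−1)(c−1) df. Undefined levels are excluded.

## Composition and bootstrap

Per-sample trait composition is computed in two weightings: by reads
(category reads / sample reads — a community-weighted mean with read count
as the abundance proxy) and by MOTUs (category presences / presences).
Period composition is the unweighted mean of per-sample shares,
renormalised; this treats samples as the replication unit, matching the
bootstrap. Uncertainty comes from a stratified bootstrap (default
B = 1000) that resamples sample ids with replacement within each period
and takes the 2.5/97.5 percentiles (plain percentile method, linear
interpolation; no BCa). Periods with one sample yield width-zero intervals
and are flagged.

## PERMANOVA

Distances are Bray–Curtis for compositional responses and Euclidean for
ordination scores. Squared distances are Gower-double-centred,
G = C(−½ D∘D)C with C = I − 11ᵀ/n, and sequential (Type-I) sums of squares
for an ordered term list come from nested hat matrices:
SS_k = tr(H_k G) − tr(H_{k−1} G). Pseudo-F per term uses the residual mean
square of the full model. p-values use free permutation of observations
(no strata), p = (#{F* ≥ F} + 1)/(n_perm + 1) with ties counted as ≥
(conservative); n_perm defaults to 999 and an exact-enumeration mode
exists for n ≤ 9. Under a Euclidean distance and one factor the pseudo-F
reduces exactly to the classical one-way ANOVA F, which the tests verify
to 1e-9 (and cross-check against scikit-bio's one-way PERMANOVA).
Pairwise contrasts rerun the one-factor test on subset matrices,
unadjusted by default (Holm available), and are summarised by a compact
letter display built from maximal cliques of the "not significantly
different at α = 0.05" graph. Terms aliased with earlier covariates can
either raise or be retained with df = 0 and zero SS plus a warning; the
trait-niche models use the latter so that a perfectly confounded trait
reports zero added variance.

## OMI ordination

The environment table contains indicator columns for *all* period levels,
centred and standardised with uniform sample weights 1/n (population
scaling, as in the ade4 default). For species i with profile
p_ij = y_ij/y_i+, the marginality is m_i = Σ_j p_ij z_j; OMI_i = ‖m_i‖²;
tolerance is the profile-weighted variance of sample projections on the
marginality direction; residual tolerance closes the identity
inertia = OMI + tol + rtol (exact, asserted at 1e-9). Ordination axes are
eigenvectors of MᵀUM with U = diag(y_i+/y_++), so Σ eigenvalues equals the
abundance-weighted mean OMI; for a three-level factor the environment has
rank 2 and eigenvalues beyond the second vanish. Axis signs follow the
interpretation convention that the post-LGM sample centroid is negative on
axis 1 and the LGM centroid negative on axis 2.

The randomization test permutes the sample-to-environment assignment (one
global row permutation of the environment table, preserving the community
covariance structure) and recomputes the weighted mean OMI;
p = (#{perm ≥ obs} + 1)/(n_perm + 1). The permutation scheme and count
(999) are package choices; the alternative of permuting within-species
profiles is deliberately not used because it destroys sample structure.

Trait–niche models run Euclidean-distance PERMANOVA on the two
retained axis scores: (i) each trait alone; (ii) growth form first, the
focal mutualist trait second; (iii) growth form plus the non-confounded
mutualist traits first, the focal trait last. Mycorrhizal type and status
are partially confounded and never co-entered; where a model needs one of
the pair as a covariate, status is used. Per-axis category contrasts use
Dunn's rank test with mid-rank ties and the tie correction
T = Σ(t³−t)/(12(N−1)), two-sided normal p-values, unadjusted by default.

## Spatial diagnostics

Great-circle distances use the haversine formula with Earth radius
6371.0 km. Default distance classes are [0, 200, 500, 1000, 2000, ∞) km,
anchored to the short-range (< 200 km) and long-range (> 2000 km) scales
of interest. The Mantel correlogram statistic per class is the
standardized correlation, over all pairs, between the in-class indicator
and the *residual* ecological distance, sign-inverted so that positive r
means similarity within the class; residual distances are obtained by
projecting the period effect out of the Gower matrix (the distance-based
RDA residual) and re-expressing R as pairwise distances. Permutation
p-values are two-sided on |r| and Holm-adjusted progressively, nearest
class first. Multi-scale ordination decomposes, per class, the
variogram-style variance of the observed composition into
explained-by-period, residual, and a cross term that vanishes under
scale-independent trait–environment correlation; over a single all-pairs
class it reduces to the classical between/within partition with
denominator n−1. The Type-I inflation estimate is simulation-based: null
responses are drawn from a Gaussian process over the observed coordinates
with exponential covariance (sill, range, nugget), one-way PERMANOVA is
run per draw, and the rejection fraction at α = 0.05 is reported with a
Wilson interval. With sill 0 the procedure is calibrated (rejection
≈ 0.05); inflation appears when the period factor is spatially aligned.

## Phylogeny

MOTUs are placed on an ultrametric backbone species tree: single-species
MOTUs relabel their backbone tip; multi-species MOTUs gain a new tip at
the MRCA of the backbone members of the lowest taxonomic rank (genus,
tribe, subfamily, family) containing all component taxa. MRCA generalises
the rank node when the rank is non-monophyletic; if the rank has one
backbone member the parent node is used. The pendant branch length equals
the attachment node's height, keeping all tips contemporaneous, so
grafting preserves ultrametricity and tree height; redundant species are
pruned afterwards. Unplaceable MOTUs are reported, never dropped silently.

Phylogenetic GLS scales the off-diagonal of the Brownian covariance C by
Pagel's λ (diagonal kept). λ is estimated by bounded ML on [0, 1]
(profile likelihood, tolerance 1e-6, endpoints checked); ML rather than
REML is used for simplicity and because only λ's location matters here. On
a star tree λ is unidentifiable and reported at the lower bound with a
flag. Coefficient standard errors use the unbiased residual variance
(n − p denominator). Category niche means are cell-means GLS coefficients
under V(λ̂) next to arithmetic means ± SE; with λ̂ = 0 and contemporaneous
tips the two coincide. Per-axis (not joint multivariate) models are
fitted.

## Sensitivity simulation

Error injection perturbs mycorrhizal status, mycorrhizal type (except
ERM) and pollination; ERM assignments and N-fixation are treated as
phylogenetically conserved and never altered. For each susceptible trait,
round(rate·S) MOTUs are drawn without replacement (rounding is a package
choice) and reassigned uniformly among the other permitted levels, with
ERM never a target. The NM coupling rule keeps the type/status invariant:
type→NM drags status to NM; type leaving NM sends an NM status to a
uniform OM/FM draw; status→NM forces type to NM (so ERM-typed MOTUs are
not offered NM status); status leaving NM sends the type to a uniform
AM/ECM draw. Traits are perturbed independently within a replicate.
The robustness curve Pearson-correlates the flattened per-sample
read-weighted shares of the susceptible traits against the original
(protected traits are constant and excluded from the vector); the model
rerun recomputes the most conservative trait–niche model (focal trait
after growth form and non-confounded traits) per replicate and reports
median R² and p.

## Synthetic data generator

The generator reproduces the structural features the statistics consume:
216 samples split 145/32/39 over the three periods, 131 MOTUs, 21 sites,
category marginals equal to the published counts/131, trait–trait
correlation induced by conditioning mycorrhizal type, status, N-fixation
and pollination on growth form (woody MOTUs biased towards ECM/ERM and
wind pollination; N-fixers drawn only among mycorrhizal MOTUs, so no NM
fixer exists), period-dependent log-fold abundance shifts matching the
reported directions (AM/forbs/OM declining towards the post-LGM, ECM/NM
and wind pollination increasing, N-fixers dipping in the LGM),
Dirichlet-multinomial counts (concentration 0.3·n_motus, mimicking
metabarcoding overdispersion), lognormal read depths (log-mean 8.9,
log-sd 1.5, giving a mean depth near the study's ≈ 23,000 reads/sample),
and spatially autocorrelated site effects from an exponential-covariance
Gaussian process (range 200 km, sill 0.25) entering through a random MOTU
loading vector. Phylogenetic trait conservatism is optional: growth form
follows quantile bins of a Brownian character simulated on a Yule tree
over the MOTUs (λ = 0.5 by default). The truth record stores the exact
per-sample expected category shares, so period-share estimators and CI
coverage can be validated analytically.

What the generator does **not** emulate: PCR and sequencing bias,
taphonomic loss, taxonomic mis-assignment, uneven temporal coverage within
periods, or real trait–phylogeny structure beyond the single conserved
character. Passing tests therefore establish the correctness and
calibration of the statistical machinery under the stated generative
model, not the field accuracy of trait assignments or the published
effect sizes, which require the original supplementary data.

## Problem sizes and numerical choices

The test suite calibrates the stochastic procedures at reduced but
representative sizes chosen to give tight Monte-Carlo error: PERMANOVA
Type-I over 1000 null datasets (n = 24, 99 permutations), the OMI
randomization and per-class Mantel tests over 500 each, bootstrap
coverage over 200 replicates at 40 samples/period, λ recovery over 100
replicates of 200-tip trees, and sensitivity monotonicity over 1000
replicates per rate at the study's 131-MOTU scale. Degenerate inputs are
handled explicitly: all-zero samples and zero-read MOTUs are rejected with
the offending label, single-level factors raise, all-tied Dunn inputs give
z = 0 and p = 1, empty correlogram classes are reported without a test,
near-singular GLS covariances receive a minimal diagonal jitter (points
that remain singular are excluded from the λ search), and a
non-positive-definite spatial covariance is jittered with a warning.

## Known limitations

* The randomization scheme of the OMI Monte-Carlo test and the exact
  construction of the published correlogram/MSO supplement are not fully
  specified by the source analysis; the implementations here are
  documented interpretations and are validated by calibration rather than
  by value-matching.
* Pairwise PERMANOVA and Dunn p-values are unadjusted by default; Holm
  adjustment is available by flag.
* PGLS is per-axis and univariate; multivariate PGLS and
  Ornstein–Uhlenbeck models are out of scope.
* The published headline statistics (Tables 1–3 values, Fig. 1
  proportions) depend on the original supplementary data table, which this
  package does not ship; they are reproduced structurally on synthetic
  data only.
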