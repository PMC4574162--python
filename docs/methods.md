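# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of `crossnet`. Everything
stated here is computed by the test suite or by `scripts/acceptance.py`;
nothing is quoted from external data.

## Study design being emulated

The package targets genetical-genomics data from an F2 line cross between
two divergent founder breeds (the defaults mirror a Duroc × Pietrain pig
resource population): ~171 F2 animals, 124 microsatellite markers on 19
linkage groups (3–9 per group), phenotypes recorded with sex, slaughter
group and carcass weight as systematic effects, and two-channel
microarray expression with dye, sex and hybridisation-array effects.
Scan positions are every marker plus k = 11 equidistant pseudo-positions
per marker interval; for the default map this gives exactly
124 + 11·(124 − 19) = 1,279 positions.

## Breed-of-origin probabilities

Founder breeds are assumed fixed for alternative alleles, so marker
genotypes are fully informative for breed origin. At a marker the state
probabilities (P11, P12, P22) are 0/1 indicators of the observed state.
At a pseudo-position they are the conditional distribution of the origin
state given the two flanking marker states: per gamete, the
phase-consistent flanking-allele assignments are enumerated and weighted
by Haldane transmission probabilities (r = ½(1 − e^(−2d/100)); no
interference), the interior-allele probability is the standard three-point
conditional, and the two independent gametes are convolved. Because only
two flanking markers enter, this is exact between adjacent markers under
full informativeness; it is *not* the multipoint pedigree-based machinery
needed for partially informative real microsatellites, which is out of
scope. Missing flanking genotypes fall back to single-flank conditioning
(default) or NaN ("drop" mode). The additive coefficient is c = P11 − P22;
note that the common verbal gloss "expected number of breed-1 alleles"
describes c + 1 — the formula, with range [−1, 1], is what the models use.

## Phenotype scan

Full model y = μ + sex + group + carcwt·β + c·α + e versus the reduced
model without c·α, compared by the exact F-test with (1, n − p) degrees of
freedom. The whole-genome scan residualises the trait and all c columns
on the covariates once (Frisch–Waugh), which is algebraically identical to
refitting both models at every position (unit-tested against an explicit
two-regression oracle). Positions where c is conditionally constant are
reported untestable (NaN), as is a constant trait.

Genome-wise 5 % thresholds use permutation tests in the
Churchill–Doerge style: the animal→genotype assignment is permuted
jointly across all positions while trait and covariates stay fixed, the
maximum F over the genome is recorded per permutation, and the threshold
is the empirical 95th percentile (type-7 linear interpolation; ties and
small permutation counts therefore behave exactly like `numpy.quantile`).
Permutations default to 1,000 and always require a seed; an explicit
permutation list can be supplied (used by the exhaustive n = 5 oracle
test). Measured genome-wise type-I error at reduced scale (200 null
studies × 200 permutations) sits within Monte-Carlo error of 5 %
(acceptance suite).

## Expression scan

Mixed model w = μ + dye + sex + c·α + array + e with the array a Gaussian
random effect, fitted by **maximum likelihood**, not REML, because the
LRT compares models with different fixed effects. With at most two
animals per array, rotating each pair into mean and difference components
diagonalises V = I + λZZ′, so the likelihood profiles over the single
variance ratio λ = σ²_a/σ²_e with a closed-form weighted-least-squares
inner step; λ is optimised by bounded scalar minimisation to 1e−8 and
checked against the λ = 0 boundary (flagged, collapsing to OLS). The fit
is verified against a dense grid-search profile oracle and against
statsmodels' MixedLM (ML) on fixtures. The LRT is referred to χ²(1)
(the tested term is a fixed effect; no boundary correction), and its null
rejection rate is verified near 0.05.

FDR control uses Benjamini–Hochberg step-up q-values across the entire
probe × position family (delegated to statsmodels, verified against an
O(m²) brute-force oracle), with eQTL called at q ≤ 0.20 at the probe's
best position. One property deserves emphasis: BH controls the expected
false discovery proportion *among position tests*; calling a probe
significant because its minimum q over many correlated positions passes
the threshold is a selection step, and the probe-level false-call
proportion is correspondingly higher (measured ≈0.4–0.5 with 40 null
probes and 5 strong cis signals). Power is unaffected — strongly
cis-regulated probes are always recovered in the test conditions — but
probe lists at FDR 0.20 should be read as candidate sets, as in the
original application.

## Co-localization

"Region" is given an operational definition (the source analyses located
regions visually): per trait and linkage group, the most significant
position exceeding the trait's genome-wise threshold is a peak; peaks are
clustered greedily, most significant first, absorbing all peaks and all
significant eQTL best positions on the same linkage group within
window_cm = 20 (configurable); regions failing the minimum pQTL/eQTL
counts are dropped. The anchor is the seed peak, labelled
"@<group>.<within-group index>". The per-region learning dataset bundles
the anchor's c vector with phenotypes adjusted by sex + group + carcass
weight (OLS residuals) and expression adjusted by dye + sex fixed effects
and the array random effect's BLUP under the ML variance estimates.
Whether the original adjustment removed array effects as fixed or
predicted random effects is not stated anywhere; BLUP removal was chosen
as the analogue of the random-effect scan model.

## Structure learning

Fisher's Z test on partial correlations (precision/Schur-complement form,
cross-checked against residual-regression) drives two learners:

- **IC** (exhaustive reference): an edge A–B survives if *no* subset of
  the remaining variables separates the pair at level α (subsets
  enumerated by size, deterministically); unshielded triples A–C–B become
  colliders when no separating set *containing C* exists; Meek rules
  R1–R4 propagate orientations.
- **IAMB**: grow–shrink Markov-blanket estimation per variable (largest
  |Z| first, ties by name; shrink removes members independent given the
  rest), AND-rule symmetrisation, then neighbour resolution by searching
  separating sets within the *union* of the two blankets. The union
  pool, rather than the smaller blanket alone, is used deliberately: a
  finite-sample blanket that is too small degenerates the search to a
  single marginal test and retains spurious edges the exhaustive search
  would remove; with the union pool the two learners return identical
  PDAGs on ≥95 % of faithful 8-node simulations at n = 10,000
  (acceptance suite).

Prior knowledge enters as constraints: genotype exogeneity (no edge into
a genotype node; on by default — a germline genotype is fixed before any
trait exists), whitelisted directed edges and blacklisted
edges/directions. Conflicting v-structure orientations leave the
contested edges undirected and are logged, not fatal. Meek R4, which
only fires under injected background knowledge, is implemented in the
form: orient a−b as a→b when there are c→d and d→b with a adjacent to
both c and d and b, c non-adjacent (if b→a held, acyclicity would force
d→a and then c→a, creating a new unshielded collider c→a←b).

Two finite-sample facts shape what "recovery" can mean at fixed α:
false extra edges persist at rate ≈ α per d-separated pair regardless of
n (all separating-set tests share essentially the same residual-
correlation fluctuation, so testing many subsets does not drive the rate
down), while missed true edges and missed v-structures vanish as n grows.
Exact whole-graph identity therefore plateaus near (1 − α)^(#separated
pairs) — about 0.35 for the 11-node default topology — for *any*
fixed-level constraint-based learner. The consistency checks accordingly
assert recall: at n = 10,000 the mean recovered fraction of true skeleton
edges plus true v-structures exceeds 0.90 over 100 seeds (in practice it
is ≈0.99).

## Effect estimation, paths, stability

A fully directed DAG is required before fitting. Undirected leftovers
are resolved by priors plus the Dor–Tarsi consistent-extension algorithm
(no new v-structures, no cycles, or an error naming the blocking edges).
A learned finite-sample skeleton can be genuinely inextensible — a
chordless cycle with no declared collider admits no consistent
orientation — so a `best_effort` mode orients the blockers acyclically
anyway (new v-structures permitted, logged); the pipeline falls back to
it with a warning and records the fact in its summary.

Given the DAG, maximum likelihood factorises into one OLS regression per
node (intercept, parent coefficients, OLS standard errors, ML residual
variance with divisor n). SEs are per-local-regression; no joint
covariance across nodes is computed, which the Markov factorisation
justifies given the structure. Path decompositions enumerate all simple
directed paths (own DFS, verified against recursive brute force and
networkx); the total effect is the sum of per-path coefficient products,
and for an exogenous source equals the marginal regression slope
(verified at n = 20,000). Unbiasedness of the coefficients and ≥95 %
sign-correct anchor total effects at the study size n = 171 are asserted
in the acceptance suite.

Jackknife stability re-learns the structure on each of the n leave-one-out
datasets with identical settings and scores every full-data adjacency for
presence and, among resamples where present, for direction agreement
(same state / opposite / undirected; for a reference-undirected edge
"same" means undirected again and any directed resample counts as
"opposite"). Failed resamples are excluded from denominators and counted.

## Synthetic-data generator

The generator is the package's study stand-in, not a fixture: F2 genomes
are drawn directly as two independent F1-gamete mosaics (valid because
founders are fixed for alternative alleles, making the F0/F1 pedigree
redundant), with crossovers per Haldane; genotypes are reported at
markers and the causal position. Traits follow a linear-Gaussian SEM
rooted at the QTL node (whose value is the true c ∈ {−1, 0, 1}), in
topological order, with configurable coefficients and residual SDs.
Nuisance is layered on top: sex (±0.5 on phenotypes, 0.2 on expression),
4 slaughter groups with N(0, 0.3) effects, carcass weight N(85, 7) with
slope 0.05, dye effect 0.3, array effects N(0, 0.4). These magnitudes are
moderate relative to unit residual SD — large enough that unadjusted
analyses would be visibly confounded, small enough not to dominate; the
carcass-weight covariate is causally inert by default. The default truth
has the anchor feeding seven cis genes (|coef| 0.7–1.0, both signs), one
gene–gene edge, one direct anchor→phenotype edge, and phenotype→phenotype
edges, so that total effects on the two fat traits are positive and on
loin weight negative. Arrays pair two animals with opposite dyes (an odd
animal sits alone; a single-channel mode exists for simpler tests).

What the simulator does **not** emulate: family structure (4 sires × 15
dams induce relatedness the scan models also ignore; adding a relatedness
option remains open), partially informative multi-allelic markers,
microarray intensity-level noise (spatial artefacts, background), and
selection of traits from a larger panel. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative assumptions, not robustness to those real-data complications.

## Problem sizes and determinism

Default analysis parameters: k = 11, n_perm = 1,000, genome-wise level
0.05, FDR 0.20, α = 0.05, window 20 cM. The test and acceptance suites
run reduced designs chosen as the package's own verification scale: maps
of 1–6 linkage groups, 200 null studies × 200 permutations for threshold
calibration, 20,000 replicates for Fisher-Z calibration, 100 seeds at
n = 10,000 for structure recall, 200 replicates for unbiasedness and
sign consistency. Every stochastic stage draws from
`numpy.random.Generator` streams spawned deterministically from a single
seed; identical configuration and seed reproduce byte-identical outputs
(tested on the full pipeline summary).
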