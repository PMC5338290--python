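# Methods

## The model of the data

The object of analysis is an unweighted bipartite network: insect species
on one side, plant species on the other, an edge meaning "this insect
feeds on this plant". Interaction multiplicity is deliberately discarded —
the statistics count *relationships*, not observation frequency — and
species names are matched exactly after whitespace normalization (no
synonym resolution; curated inputs are assumed to use canonical
binomials). Taxonomy enters only through lookup tables
(species → genus/subfamily/family/order); plant chemistry through a
catalog mapping each plant species to a set of opaque compound IDs.

The chemically annotated ("real-world") network is the subgraph of edges
whose plant carries at least one cataloged compound; species isolated by
this filter are dropped. The filter is idempotent and can only shrink
degrees, which the tests assert.

## Null models and Z-scores

Every significance statement compares an observed measure X with its
distribution over randomized networks:
`Z_X = (X_real − mean(X_rand)) / sd(X_rand)`, sample SD (n−1), default
1,000 replicates.

Two randomizations are implemented, and results are always labeled with
the model used:

- **fixed_fixed** (default): a checkerboard-swap chain. Each accepted
  swap exchanges edges (a,p),(b,q) for (a,q),(b,p) when neither target
  edge exists, which preserves both degree sequences exactly and the edge
  count at every step. The burn-in attempts `swaps_per_edge × |E|` swaps
  (default 10 per edge). Networks admitting no valid swap (e.g. complete
  bipartite graphs) are returned unchanged with a log note. Exact degree
  preservation is what makes the evenness and food-pairing Z-tests
  meaningful: an insect's host count — the denominator of both
  statistics — is identical in every replicate.
- **probabilistic**: each cell (i,j) filled independently with
  probability min(1, d_i·d_j/|E|) — proportional to the degree product,
  scaled so the expected edge count equals the observed one before
  capping. Degrees are preserved in expectation only. The per-cell
  occupancy is verified against the specified probabilities by
  Monte-Carlo.

One master seed spawns per-replicate child seeds
(`numpy.random.SeedSequence.spawn`), so any replicate is reproducible in
isolation and two runs with the same seed are identical. A null ensemble
with zero SD yields a flagged *degenerate* result (printed `NA`), never an
infinite Z.

When several statistics are tested on the same network (the global test
plus per-family and per-subfamily panels), they are evaluated on **one**
shared replicate stream — cheaper, and the resulting Z panels are
coherently correlated rather than independently noisy.

## Family-based evenness (feed-on-family test)

For insect category i (a species, or a pooled subfamily/family) with S_i
family-resolvable host plants, N_ij of them in plant family j:

    E(i) = − Σ_j (N_ij / S_i) · ln(N_ij / S_i) / ln |m_f|

with natural logarithms and m_f the set of plant families present in the
*whole* network, not per category — this keeps E comparable across
categories. Conventions: 0·ln 0 := 0; a single used family gives E = 0;
|m_f| = 1 gives E := 0 (entropy and its maximum both vanish —
continuity). E = 1 exactly when hosts spread uniformly over all |m_f|
families. Edges whose plant lacks a family are excluded and counted in
the log, not imputed. The global test statistic is the unweighted mean of
species-level E over insect species; Z^E < 0 means feeding is more
family-selective than the degree-preserving null.

## Food pairing (feed-on-compound test)

For butterfly k with n ≥ 2 compound-annotated hosts, N_s(k) is the mean
of |C_a ∩ C_b| over the n(n−1)/2 unordered host pairs. Species with
fewer than two annotated hosts are *excluded* from the across-species
mean (a pair average over zero pairs is undefined; zero-filling would
bias the test toward the null); the exclusion count is reported. Under
fixed_fixed the eligible species set is constant across replicates, since
degrees are conserved. Z^Ns > 0 means hosts share more compounds than
degree-matched chance.

## Compound contribution χ

For plant i with herbivore set A(i) (f_i = |A(i)|), χ_i = T1 − T2:

- T1: over herbivores k ∈ A(i) with at least one other host, the mean of
  (1/(|P(k)|−1)) Σ_{j∈P(k), j≠i} |C_i ∩ C_j| — the observed average
  compound overlap between i and the plants its herbivores also eat.
  Single-host herbivores carry no pairing information and are excluded
  from both numerator and denominator (an average over eligible terms is
  unbiased under no selectivity; if no herbivore is eligible, T1 := 0).
- T2: (1/(|P|−1)) Σ_{j∈P, j≠i} |C_i ∩ C_j| over all other plants in the
  network — the same overlap expected if insects fed without selectivity.

χ = 0 exactly under complete-bipartite feeding (T1 ≡ T2) and for plants
with no compounds; its network mean is zero within Monte-Carlo error
under random feeding. The mean host count S(i) of A(i) is stored with
each result for transparency although the coefficient does not use it.
χ is reported per plant together with degree (f_i) and the average
neighbour degree (mean number of host-plant families used by the plant's
herbivores), plus the Spearman correlation of χ against degree
(suppressed below 3 plants or at zero variance).

## Enrichment screen for common-specific compounds

Per compound and insect clade, a 2×2 table — clade vs non-clade
observations × compound present/absent in the observation's plant — with
a two-sided Fisher's exact p (conditional hypergeometric; verified
against exhaustive enumeration over all tables with n ≤ 30) and
Cramér's V = sqrt(χ²/n) from the *uncorrected* Pearson χ² (a continuity
correction would break the p↔V↔n correspondence used to calibrate the
threshold); V := 0 when a margin is empty. The default observation unit
is the plant–herbivore relationship; because relationship rows are not
independent (one plant contributes one row per herbivore), a
plant-species unit is offered and the caveat is logged on every
relationship-unit run. The default decision rule is a fixed
effect-size-calibrated threshold (p < 10⁻⁶, chosen for V ≈ 0.6 at
n ≈ 900-relationship scale); Benjamini–Hochberg is an explicit opt-in,
not the default.

A separate exact partition classifies compounds given a host set and a
disjoint background set: present in every plant of both → *common*;
present in every host and absent from every background plant → *common
specific*; everything else → *other*.

## Synthetic data: what it emulates and what it does not

The generator builds a balanced taxonomy (default 4 plant families × 25
plants; 5 insect families × 2 subfamilies × 5 species), layered chemistry
(1 globally common compound; 5 family-core compounds per plant family; 1
clade-specific compound per insect family planted into the plants of its
designated plant family/families; 30 background compounds sprinkled
independently at rate 0.05), and a network in which each insect species
draws 5 hosts without replacement with probability ∝
exp(λ·1[plant in preferred family] + β·1[plant carries the clade's
planted compound]). Preferences act as exponential tilts on log-weights,
giving one smooth family from uniform feeding (λ = β = 0) to
deterministic feeding — this is what makes monotonic parameter-recovery
tests possible. Defaults λ = β = 2 represent moderate, simultaneously
present family- and compound-selection, the regime the statistics are
designed to dissect; per-clade overrides allow heterogeneous selection
strengths; `clade_compound_families > 1` plants a clade's compound across
several plant families (compound-coherent but poly-family-phagous
feeding); `clade_compound_plant_fraction < 1` makes within-family
chemistry heterogeneous, which is the regime where compound-following
produces the positive χ-vs-degree relationship (plants carrying the
attractant gain both herbivores and overlap; with chemically uniform
families that correlation has no source of variation and is ~0).

Not emulated: phylogenetic branch lengths, abundance-weighted
interactions, spatial structure, compound-count heterogeneity within a
layer, and database artifacts (synonyms, partial annotation bias).
Passing tests therefore show that the statistics detect the planted
mechanisms at realistic sizes and are correctly calibrated under the
null; they do not certify behavior under real-data artifacts such as
strongly skewed degree distributions or annotation bias toward
well-studied plants.

Ground truth (preferred families, planted compounds, per-edge generative
log-weights, config echo) is serialized beside the data and round-trips
exactly; fixtures are deterministic and byte-identical for a given seed.

## Problem sizes used by the test suite

Null-model-heavy checks run on a reduced configuration (3 plant
families × 10 plants, 3 insect families × 2 subfamilies × 3 species, 4
hosts/species) chosen so that 50-replicate calibration runs and the 3×3
(λ, β) recovery grid execute in a few minutes while keeping ≈70-edge
networks with non-trivial degree structure; the grid uses 200 null
replicates per Z (Z precision ≈ 0.07 SD, ample for rank tests on cell
means). Structural and oracle checks (degree preservation, entropy, pair
enumeration, Fisher) run at full printed scale. The acceptance script
uses the full default sizes with 1,000 null replicates.

## Numerical choices and edge cases

- Sample SD with n−1 denominator throughout; immaterial at 1,000
  replicates but fixed for reproducibility.
- Degenerate nulls flagged, never ±inf; tables print NA.
- Iteration orders are sorted wherever floating-point accumulation or
  output ordering could otherwise depend on set iteration order, so
  results are identical across processes regardless of hash
  randomization.
- Delimiters auto-detected between tab and comma with explicit override;
  header rows mandatory; duplicate interaction rows collapse to one edge;
  conflicting taxonomy rows are an error naming the species.
- Pipeline exit codes: 0 success, 2 validation/config failure, 3 stage
  failure (failed stage named, earlier outputs preserved).

## Known limitations

- The fixed_fixed chain is a burn-in heuristic (10 attempted swaps per
  edge); for pathological degree sequences mixing could be slow, though
  the calibration tests show no detectable bias at the sizes used.
- Relationship-unit enrichment p-values are anti-conservative under
  non-independence of rows; use the plant unit or the BH option when
  that matters.
- Species name matching is exact; synonym-ridden inputs must be cleaned
  upstream.
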