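# Methods

This note documents the statistical procedures ribovar implements, the
modelling assumptions behind the synthetic-data generator, the numerical
conventions, and the design decisions taken where several reasonable choices
existed.

## Data model

The unit of observation is a **cloned rRNA gene copy**: one sequence from
one specimen's multicopy rRNA array. Sequences nest in specimens, specimens
in populations (sampling localities), populations in oceanic basins. Every
unordered sequence pair therefore belongs to exactly one comparison level:
intra-genomic (same specimen), population (same population, different
specimens), regional (same basin, different populations) or geographical
(different basins). Metadata additionally records an invasion status
(native, established invader, invasion front, outgroup) and a genotype
lineage label, so basin-level contrasts and invasion-status contrasts can be
run on the same nesting.

## Gap and ambiguity handling

Alignment columns containing gaps or IUPAC ambiguity codes are handled by a
site mask. The default policy is **complete deletion**: a column is usable
only if every sequence has a plain A/C/G/T there. This mirrors the behaviour
of the standard haplotype-network tools, and it makes haplotype identity,
segregating-site counts and pairwise difference counts mutually consistent
(all are evaluated on the same columns). Pairwise deletion is available
behind a flag; under it π keeps the full column count as denominator, so it
should be treated as a sensitivity check rather than a headline number.
Subset analyses (per-genotype, per-basin tables) recompute the mask on the
subset, so the usable length Lᵤ legitimately differs between rows of a
summary table.

## Diversity statistics

For n sequences on Lᵤ usable columns: S is the number of usable columns with
two or more distinct A/C/G/T states; k̄ is the mean number of pairwise
differences computed from the sequences themselves (not from haplotype
frequencies, so unequal haplotype sampling is weighted exactly);
π = k̄ / Lᵤ. Haplotypes are equivalence classes of identity on usable
columns, ordered by decreasing frequency with ties broken by first
occurrence in the alignment, which makes all outputs order-deterministic.

Tajima's D uses the 1989 constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂) and
D = (k̄ − S/a₁) / √(e₁S + e₂S(S−1)). Significance is the classical beta
approximation: D is rescaled onto its attainable range [D_min, D_max] and
compared with a mean-zero, variance-one beta density; the reported p is the
two-sided tail. With S = 0 the statistic is reported as undefined (never as
0); groups with n < 4 are likewise flagged. The statistic requires n ≥ 4.

## AMOVA

The nested analysis of molecular variance follows the Excoffier-type
decomposition of squared distances δ² into among-basin, among-population-
within-basin and within-population sums of squares, with unequal-sample-size
coefficients (n₁, n₂, n₃) in the expected mean squares and a method-of-
moments solve for σ²ₐ, σ²_b, σ²_c.

**Distance semantics.** By default the raw count of pairwise nucleotide
differences is used directly as δ² (`delta="count"`), the convention of the
standard network/AMOVA tools in this field, where the difference count is
already treated as a squared Euclidean surrogate. `delta="squared-count"`
squares the counts first; both are exposed because published tables rarely
state the convention.

Percent variation is reported unclamped — negative components are genuine
artifacts of the moment solve and are additionally shown clamped to 0 in the
report layer, matching how such tables are conventionally annotated. Φ_ST,
Φ_SC and Φ_CT follow the usual definitions; when total variance is not
positive the Φ values are flagged undefined rather than forced to a number.

**Permutation significance.** Φ_ST permutes individual sequences among
populations (basin labels travel with the population assignment); Φ_SC
permutes individuals among populations within their basin; Φ_CT permutes
whole populations among basins. p = (#{Φ_perm ≥ Φ_obs} + 1)/(n_perm + 1), so
p is never 0. The default is 1000 permutations and a seed is mandatory.
A basin structure in which every basin holds a single population collapses
the middle stratum; the model refuses it and points the caller at the
one-level (populations-only) variant.

## Median-joining networks

The minimum spanning network is computed by a Kruskal-style sweep over
distance thresholds: at each threshold all edges of that weight (within the
relaxation ε) joining components that were distinct when the threshold was
entered are admitted, which yields exactly the union of all minimum spanning
trees at ε = 0. The median-joining iteration generates candidate median
vectors from node triplets carrying at least two mutual links in the current
network; the sitewise median is the majority state, and where all three
states differ the state of the triplet member closest to the other two is
used (ties broken lexicographically). Per iteration the single candidate
that most reduces the total connection cost — the minimum-spanning-tree cost
of the node set, used as the λ criterion — is added; the loop stops when no
candidate reduces the cost. Obsolete medians (degree ≤ 2 whose removal
leaves the minimal connection cost unchanged) are pruned to a fixed point.

Determinism is guaranteed by sorted node, triplet and candidate orderings;
identical input yields byte-identical GraphML. On small binary instances
(up to 5 haplotypes over 6 sites) the added median set provably coincides,
in our test sweep, with greedy cost-reducing Steiner points found by brute
force over all candidate vectors. On large datasets a single-best-candidate
greedy step may in principle diverge from implementations that batch-add
feasible medians within a λ tolerance; ε > 0 relaxes the sweep exactly as in
the published algorithm.

## Patristic stratification

Patristic distances are path sums of branch lengths, which are invariant to
root placement, so arbitrarily rooted newick inputs are treated identically.
Distances enter the Fig.-style level summaries untransformed; the square
root transform belongs to the dispersion analysis only. Pairs crossing
genotypes are retained with pair labels so per-genotype panels can filter to
within-genotype pairs; levels with zero pairs for a genotype are reported
with n = 0 rather than dropped.

## Beta dispersion

Pairwise (patristic) distances are square-root transformed, double-centered
(Gower) and eigendecomposed in full. Negative eigenvalues are retained on
separate axes: squared distance to a group centroid is the squared Euclidean
distance on positive axes **minus** that on negative axes, the convention of
the classical multivariate-dispersion method; the rare negative squared
value is floored at 0 with a logged warning. The ordination is built once on
the full matrix and centroids are always per specimen, so z measures
intra-genomic spread; higher-level factors (basin, invasion status) only
group the z values. An `intra_only` variant computes each specimen's scores
from its own submatrix in closed form, for sensitivity analysis when the
between-specimen geometry should not influence the scores.

The sequential (Type I) ANOVA enters factors in caller order — canonically
(basin, population, specimen) — via incremental least-squares projections;
degrees of freedom are rank increments, so the nested, collinear dummy
blocks are handled exactly, and R² per factor plus the residual sums to 1.

Pairwise comparisons use two-sided rank-sum tests: the exact null
distribution when both groups have ≤ 25 observations and no ties, otherwise
the normal approximation with tie and continuity corrections. Holm step-down
adjustment is the default (Bonferroni and none are available), and the
significance tiers are `*` for adjusted p < 0.05 and `**` for p < 1e−6.
**Test unit.** By default each specimen contributes its mean z once. Clones
of one genome share a centroid — with two clones their z values are
identical by construction — so sequence-level rank-sum tests are
pseudo-replicated; in a null calibration (no basin effect, 200 simulated
datasets) sequence-level testing rejected at ≈ 0.17 instead of 0.05, while
specimen-level testing is calibrated within [0.02, 0.08]. Sequence-level
testing remains available (`unit="sequence"`). The ANOVA intentionally stays
at sequence level, where the nested specimen factor absorbs the dependence.

## The simulator

A forward-time Wright-Fisher-style model of a multicopy gene family.
Each individual carries C copies of an L-site sequence (states A/C/G/T).
Per generation and population:

1. **Reproduction** to the epoch's target size. Clonal: the offspring copies
   one parent's whole pool. Sexual: the offspring's C copies are drawn
   without replacement from the union of two random parents' pools. Mixed:
   each offspring is clonal with probability `clonal_fraction`. With
   probability `migration_rate` an offspring's parent(s) are drawn from the
   designated source population (continuous re-seeding).
2. **Mutation**: each site of each copy mutates with probability μ to a
   uniformly chosen *different* nucleotide (Jukes-Cantor-like; no indels —
   downstream statistics use difference counts only).
3. **Gene conversion**: each copy is overwritten, with probability γ, by a
   uniformly chosen other copy of the same genome (whole-copy conversion;
   tract-based conversion would be a refinement, not a change of signature).
   Events are exact Bernoulli draws; when several hit one genome in one
   generation they are resolved sequentially.

Copy number is conserved at C through every event. Sampling emulates the
clone library: a fixed number of specimens per population and k clones per
specimen drawn without replacement from the C copies (k ≤ C enforced).
All randomness flows from one PCG64 generator seeded by the config;
per-replicate seeds are derived by SeedSequence spawning, so runs are
reproducible across platforms.

Key dynamics worth knowing when interpreting output:

- In **sexual** populations copies mix between genomes every generation, so
  intra-genomic diversity tracks population diversity regardless of γ.
- In **clonal** populations without conversion the copy lineages within a
  genome can never coalesce; intra-genomic divergence grows with time and
  the intra/inter distance ratio drifts slightly **above** 1 (specimens of
  one clone family share recent ancestry, shrinking between-specimen
  distances). Homogenization therefore requires conversion, not clonality —
  clonality only stops sex from re-inflating copy diversity.
- Conversion at rate γ coalesces a copy pair at rate ≈ 2γ/(C−1) per
  generation, giving a homogenization timescale that can be set against the
  population's age.

### Scenario presets (defaults and why)

All geographic presets share μ = 1e−4 per site per generation, L = 300,
C = 6 copies, and clone-library sampling of 10 specimens × 5 clones (12 × 4
for the standalone `red_sea`); with the copy-level effective sizes used this
puts among-specimen π at a few times 10⁻², the order observed in rRNA clone
libraries of this kind.

- `neutral_null` — one population of 30 individuals (C = 2), sexual, γ = 0,
  600 generations (≈ 10 × the copy-level effective size, enough for
  mutation-drift equilibrium from a monomorphic start), μ = 3e−4, sampling
  25 specimens × 1 clone. A finite-sites control whose Tajima's D is centred
  near zero: mean D over 1000 replicates falls well inside (−0.25, +0.25).
- `indian_ocean` — stable sexual population of 80, γ = 0: the native-range
  baseline in which intra-genomic ≈ population-level variability.
- `red_sea` — 440 generations at size 60, an 8-generation crash to 4, then
  re-expansion to 400 for the last 152 generations: the postglacial
  re-colonization history. The expansion must overshoot the ancestral size —
  rare new variants accumulating on the star-like post-bottleneck genealogy
  are what drive Tajima's D strongly negative (mean ≈ −1.1 over 200
  replicates); re-expanding only to the original size leaves D near or above
  zero because the bottleneck prunes rare variants faster than they return.
  Reproduction is mixed with `clonal_fraction = 0.9` and γ = 0.08: partial
  suppression of sex with moderate conversion, strong enough that the
  homogenization timescale (≈ 30 generations) beats the sexual re-mixing
  rate, giving the intermediate intra-genomic phenotype.
- `mediterranean_invasion` — the three-basin bridgehead world: the stable
  Indian-Ocean source; a Red Sea deme founded from it at generation 440
  through a 6-individual bottleneck (same mixed/conversion regime as the
  standalone preset); and a Mediterranean deme founded from the Red Sea at
  generation 560, fully clonal with γ = 0.4 and 10% per-generation
  re-seeding from the source. Conversion homogenizes an invader genome in
  ≈ 8 generations while migration keeps supplying diverged genomes, so
  intra-genomic dispersion collapses while among-specimen diversity in the
  sink tracks the source (median sink/source ratio ≈ 1.0 across datasets;
  individual datasets scatter roughly ±40% around it).

The headline verification asserts that the per-basin median
distance-to-centroid orders Mediterranean < Red Sea < Indian Ocean in ≥ 90%
of 100 simulated datasets (observed ≈ 97%), and that the sink/source
among-specimen diversity ratio stays within 50% of unity in the median
across datasets (per-dataset ratios are noisy at 10 specimens, so the check
is on the aggregate).

### What the generator does and does not emulate

It reproduces the features the statistics rely on: multicopy sampling nested
in specimens/populations/basins, copy homogenization by conversion,
demographic signatures in the site-frequency spectrum, and source-sink
migration. It does **not** model indels or alignment error, rate variation
across sites, tract-based conversion, selection (so a selective sweep —
observationally similar to a bottleneck here — is outside generative scope),
or the trimorphic foraminiferal life cycle (sex is abstracted as pooling two
parents' copy sets). Passing tests therefore demonstrate correctness of the
statistical machinery and qualitative reproduction of the mechanism's
signatures, not quantitative fidelity to any particular empirical dataset.

## Numerical conventions

- Alignment columns are 1-based in all outputs (biological convention).
- Haplotype, node, triplet and group orderings are all deterministic
  (frequency-then-first-seen, or lexicographic), so outputs are
  reproducible byte for byte.
- Eigenvalues with |λ| ≤ 1e−10 are treated as zero axes in PCoA.
- Permutation p-values use the +1/+1 estimator; seeds are required wherever
  randomness enters (CLI enforces this).
- Degenerate inputs are refused loudly: ragged alignments, orphaned
  sequences or metadata rows, missing branch lengths, all-gap masks,
  single-population-per-basin nested designs, S = 0 for Tajima's D.

## Known limitations

- The MJN λ criterion is tied to the current minimal connection cost and
  candidates are added one per iteration; published batch-adding
  implementations can differ on large, reticulate datasets (identical on all
  small instances tested).
- Pairwise-deletion π uses the full column count as denominator, which
  underestimates per-site diversity when many columns are partially gapped.
- The permutation scheme for Φ_ST permutes individuals ignoring basins (the
  common default); alternatives exist and would change p-values on strongly
  structured data.
- Sequential ANOVA R² values depend on factor entry order by construction;
  the canonical order (basin, population, specimen) follows the nesting.
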