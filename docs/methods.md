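# Methods

## The data model

A community survey is reduced to a flux matrix `A` (habitats × species,
non-negative integers): `A[i, j]` is the number of individuals of species
`j` recorded in habitat `i` over the whole survey. The matrix is taken as
given — `coralnet` does not model observation effort, detectability or
season. Two metadata tables accompany it: a residency class per species
(resident or migrant) with an optional exclusion flag for a hyper-abundant
colonial species, and an area in hectares per habitat. All-zero rows and
columns are stripped at read time with a warning (they would put zeros in
dependence denominators); residency subsets and removal experiments may
reintroduce empty rows, which are kept and flagged so habitat-level
structures (similarity trees) retain all leaves.

## Diversity

Shannon–Wiener `H` uses the natural logarithm; this is forced by internal
consistency of the reference community's printed table, where `H`, `J` and
`S` satisfy `J = H / ln S` only in nats. Pielou's `J` is defined as 0 for a
single-species assemblage (the limiting convention; a monodominant habitat
is maximally uneven). The richness–area test is a plain Pearson correlation
with a two-sided t-test on n − 2 df; with five habitats its power is
minimal, and it is reported as a descriptive statistic, not an inference.

## Network metrics

**Connectance** is `L/(I·J)` on the binarized matrix.

**NODF** follows the overlap-and-decreasing-fill definition: an ordered row
pair (u, v) with `fill(u) > fill(v) > 0` contributes
`100·|ones(u)∩ones(v)|/fill(v)`; pairs with equal fills contribute zero;
likewise over columns; the score is the sum over both pair sets divided by
`C(I,2) + C(J,2)`. It is computed on presences only — weights never enter —
and the implementation agrees with an independent literal transcription on
random matrices (and with vegan's `nestednodf` in spot checks during
development).

**Modularity** is Barber's bipartite Q with the count matrix as weights:
`Q = (1/m) Σ (A_ij − k_i d_j/m) δ(g_i, g_j)`. The optimizer is simulated
annealing over joint habitat+species labels: module count capped at
`min(I, J) + 1` (a module containing one node class only contributes
nothing, so the cap is loss-free while letting nodes sit alone), geometric
cooling (T₀ = 0.05, factor 0.9, floor 1e-4), ten proposed single-node moves
per node per temperature, and the best of `restarts` independent runs
(default 20) is returned after re-scoring the partition from the Q formula
(the reported Q is always the formula applied to the reported partition).
At the 62-node scale of a five-habitat island community this matches
exhaustive partition search on every small random matrix tested. Annealing
is stochastic, so Q is reproducible only per seed; trajectory computations
(gradual loss) default to fewer restarts (5) because they evaluate Q
hundreds of times and the network only shrinks.

A binarized-weight variant is available (`weighted=False`); whether the
reference analysis weighted its modularity is not recoverable from the
printed value alone, which is why downstream checks use a band rather than
a point for Q.

**Habitat strength** sums species' dependences `A_ij / colsum_j` over the
habitat's row; strengths therefore sum exactly to the number of species, a
property used as a standing invariant test.

**Interaction asymmetry** averages, over a habitat's realized links, the
signed imbalance `(e−d)/max(e,d)` between the habitat's pull on the species
(`e = A_ij/colsum_j`) and the species' pull on the habitat
(`d = A_ij/rowsum_i`); positive values mean the habitat influences its
species more than it is influenced, matching the convention in which all
reference habitats score positive.

**Nested rank** orders habitats by decreasing degree (ties: decreasing
total abundance, then label) and reports `(rank−1)/(n−1)`, so the
generalist core scores 0 and the most peripheral habitat 1.

**Specificity** is a Blüthgen-style standardised specialization: the raw
index is the Kullback–Leibler divergence of the habitat's usage
distribution `p′_ij = A_ij/rowsum_i` from overall availability
`q_j = colsum_j/total`. Given fixed margins the divergence cannot exceed
`ln(total/rowsum_i)` (proof: `q_j ≥ A_ij/total` for every used species),
and that bound is attained exactly when the habitat's species occur nowhere
else, so `d′ = d / ln(total/rowsum)` maps opportunistic use to 0 and full
specialization to 1. The exact index behind the reference table is not
stated there; this formulation satisfies the table's boundary anecdotes
(a single-species exclusive habitat scores 1, proportional use scores 0)
but its point values cannot be validated without the original matrix. One
behavioural caveat discovered in testing: a habitat that dominates the
community total has `d′` pushed *down* (its usage largely *is* the
availability), so `d′` is not a monotone readout of preference
concentration.

## Similarity trees

Habitat composition distances default to Bray–Curtis on counts
(`1 − 2Σmin(x,y)/(Σx+Σy)`), with Jaccard on presences as the alternative;
clustering is agglomerative with average linkage (UPGMA) by default.
Habitats are sorted by label before linkage so the tree is independent of
input order. Empty rows in residency subsets are placed at distance 1 from
everything, keeping all five leaves in every tree. Trees serialise to
Newick with branch lengths derived from merge heights. The reference
figures' claim that the total and migrant trees coincide could not be
reproduced on synthetic surrogates (residents carry enough abundance to
perturb the total tree) and is therefore documented as a property of the
original data, not asserted by the suite.

## Habitat-loss simulation

Extinction is binary and threshold-free: a species goes extinct exactly
when its remaining column sum is zero. No rewiring, no partial-occupancy
threshold, no dispersal limitation — island birds are assumed mobile enough
to reach any remaining habitat they already use, and unable to adopt new
ones.

*Whole-habitat removal* deletes rows, applies the rule, and recomputes all
metrics on the shrunken network (zero rows/columns dropped first), with and
without the flagged colonial species.

*Gradual loss* removes `⌊f·rowsum⌋` individual observations from one
habitat's row uniformly at random without replacement (a multivariate
hypergeometric draw of the survivors); a `link` mode removes whole links
instead, since which unit the reference simulation removed is ambiguous.
Trajectories report every metric per fraction and replicate (default 10
replicates over fractions 0, 0.1, …, 1).

*Attack sequences* remove whole habitats one at a time — most/least
connected (degree order, ties by abundance then label), largest/smallest
area, or random per replicate — until none remain. R50 is the smallest
fraction of habitats removed at which no more than half the original
species survive, evaluated at step boundaries without interpolation; with
five habitats it lives on {0.2, 0.4, 0.6, 0.8, 1.0}. Deterministic
strategies repeat their order across replicates (replicates are kept for
uniform output shape; default 50). Strategies are compared by one-way ANOVA
on R50 with Tukey HSD grouped into a compact letter display
(insert-and-absorb); an all-constant input returns a degenerate flag
instead of a p-value. Note a structural fact that shapes expectations here:
with the reference degree profile (36/22/19/17/9), the two least-connected
habitats jointly host at most 26 < 28.5 species, so the most-connected
attack always crosses the 50 % line by its third step, and the
smallest-area attack can at best tie it — "least robust" among strategies
is a tie statement at this resolution.

## Synthetic communities

The generator emulates a five-habitat coral-island survey: 57 species,
migrant fraction 0.649, habitat areas (2.2, 99, 11.2, 19, 20.2) ha, and one
flagged resident "colonial seabird" holding 5 000 individuals in the forest
habitat only. Each ordinary species draws a residency class, a
truncated-geometric number of habitats (success probabilities 0.67 for
migrants, 0.28 for residents — matching the reference means of ≈1.5 and
≈2.4 habitats per species), and that many habitats without replacement,
weighted by its class's preference vector; per-link counts are discretised
log-normal `⌈exp N(2.2, 1.0)⌉`, putting the mean count per link near 15 to
match ≈1 500 non-colonial individuals over ≈100 links. Preference vectors
are the reference per-class habitat species counts raised to a
concentration exponent of 1.5: sampling without replacement flattens
realised marginals, and 1.5 is the exponent at which the realised mean
per-habitat richness best matches the reference profile (root-mean-square
error ≈1 species; both 1.0 and 2.0 are worse). Defaults were fixed by this
calibration, against the generator's structural bands (connectance
0.25–0.45, NODF 30–55, Q 0.20–0.45) and the reference degree profile, and
are not revisited per analysis.

What the generator does *not* emulate: within-class correlations between
particular habitat pairs (e.g. shorebirds favouring wetland+beach jointly),
seasonal turnover, observation error, and the exact abundance distribution
of the real survey. Consequently, tests passing on surrogates demonstrate
the pipeline's correctness and the qualitative structure of results, not
agreement with the original community's point values; surrogate-ensemble
checks of directional claims use majority-vote across ten seeds precisely
because single draws fluctuate in features (like forest–shrubland species
overlap) that the generator does not pin down.

## Numerical and interface choices

- All randomness flows from explicit integer seeds; the pipeline derives
  named substreams (modularity, gradual loss, attack) from one master seed
  via `SeedSequence`, so stages are independently reproducible and reruns
  are byte-identical.
- Degenerate shapes return NaN (NODF of a single-row network) or raise with
  the offending label named (empty rows in strength/asymmetry), never
  silently zero.
- Matrix orientation is fixed: habitats are rows, species are columns, and
  every formula in the codebase is written against that orientation.
- Outputs are tidy CSV and JSON only.

## Known limitations

- Modularity values depend on the weighted-vs-binary choice and, in
  principle, on the annealer; both are surfaced as parameters rather than
  hidden.
- The specificity index is one defensible reading of an under-specified
  metric; alternatives (resource range, degree-based specialization) would
  produce different per-habitat values.
- R50 on five habitats is extremely coarse (five possible values); it
  separates strategies, not fine gradations of robustness.
- The extinction rule ignores abundance: a species surviving on one
  individual in one habitat counts as extant.
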