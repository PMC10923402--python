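# Methods

This note documents the model, its assumptions, the tunable parameters, and the
design choices made where the design was genuinely open.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## The conditional tree and what it assumes

The joint distribution of household and member attributes is factorized along a
directed tree: zone → household size → household type → (per member) role → age
band → main activity → SPC → education, with gender attached to (role, type),
and a household branch type → income class → car ownership.  The factorization
asserts conditional independences — e.g. education ⊥ activity | (age band, SPC),
and members' free attributes mutually independent given the household frame
(type, size, roles).  These are modelling assumptions, not discoveries; they
bound which correlations the generator can reproduce.  Cross-member coherence is
imposed not through the tree but through hard structural rules:

- member 1 is the head, member 2 the spouse in couples/families, members 3+ are
  children; one-person households are type Single by definition;
- the spouse takes the gender opposite the head's;
- the head is at least `head_min_age_multi` = 21 years old (multi-person) or
  `head_min_age_single` = 18 (singles).  The two constants reflect the two
  readings of the source constraint; both are config keys;
- individuals under 18 are schoolchildren (activity student, SPC 8 inactive);
  an agent whose activity is retired carries SPC 7;
- a mother (the female of the head/spouse pair, when present) is at least
  `mother_child_gap` = 15 years older than her eldest child.  The gap value is
  a package choice (no authoritative value exists); it is a config key.

The rules enter the sampler as support restrictions (masks) of the joint, not as
post-hoc edits, with one exception: the mother–child gap involves integer ages,
which are drawn *after* the band-level chain, uniformly within the band
intersected with the member's feasible window.  When a child's window under the
gap is empty, the child's age band (and its dependent chain) is redrawn from the
restricted conditionals.  Coupling integer age to activity (a non-student's age
is drawn from the ≥18 part of the band) is what makes "under-18 ⇒ schoolchild"
hold without ever overriding a sampled activity, so band-level conditionals stay
exactly those of the tree.

## Gibbs sampling

Each zone's households are generated together, vectorized.  Free attributes (age
band, activity, SPC, education, income class, car) are initialized by a
topological (ancestral) draw from the tree under the masks and then updated with
`burn_in` = 20 systematic sweeps; each update samples an attribute from its full
conditional — its own conditional times the likelihood of its children's current
values — which for this tree involves at most three small factors.

Two consequences are worth stating plainly.  First, ancestral initialization
already samples the constrained tree exactly, so the chain starts in its
stationary distribution and burn-in sweeps preserve it; the sweeps matter in the
general case where the supplied conditionals are *inconsistent* (estimated from
different sources or levels), which is precisely when MCMC is needed.  Second,
initialization from per-attribute marginals — a plausible alternative — is
unsound here: a marginal-drawn state can be jointly impossible (a spouse
initialized as a student while spouse age bands carry no student mass), which
zeroes a full conditional.  That is why ancestral initialization is used.

The sweep order (age → activity → SPC → education → income class → car) is
fixed for reproducibility.  All randomness derives from one master seed;
per-zone substreams are keyed by a CRC of the zone id, so output is independent
of zone processing order and zones are parallelizable.

## Integerizing household counts

A zone of N individuals is decomposed into counts h₁..h₆ with Σ s·hₛ = N among
sizes of positive probability, minimizing Σₛ |hₛ − Eₛ| with Eₛ = N·pₛ/Σ s′p_s′,
ties broken to the lexicographically smallest vector.  The solver floors the
expected counts and runs a small dynamic program over bounded corrections (a
proximity argument bounds the optimal integer solution near the continuous one);
it is exact, and tested against brute-force enumeration.  When no exact total
exists (e.g. odd N with only even sizes), totals within one individual are
accepted, preferring undershoot.

## Conditional estimation

Conditionals are empirical frequency tables, not discrete-choice models: with
fixture-scale data the nonparametric estimator is unbiased, transparent and
testable.  Cells pool data at the finest spatial level reaching `min_count` = 10
observations (IRIS → commune → department → region), and record that level.
Categories of a variable rarer than `merge_floor` = 0.5% at region level merge
into the variable's designated sink category (e.g. "other unemployed").  A cell
sparse even at region level is an error by default; the pipeline enables
`conditioning_backoff`, which lets such a cell borrow the distribution of the
table with its last conditioning variable dropped (recursively, recorded as
level "backoff") — the attribute-dimension analogue of climbing the zone tree,
without which roughly one 10k-household run in ten aborts on a single rare
crossing such as education | (65–120 × SPC 2).

## Income and overweight

Income (EUR/year, 2010): α(SPC) × commune median × exp(σZ), Z ~ N(0,1), with
α(SPC) = SPC median / population median and σ = `dispersion_sigma` = 0.25.  The
dispersion restores within-cell spread (the deterministic weighting would give
every SPC × commune cell a single value); σ = 0.25 puts ~80% of draws within a
factor 1.4 of the cell value, a plausible infra-communal spread, and σ is a
config key that tests set to 0 for exact-value checks.  Floors: employed ≥
12,672 (2010 minimum wage); non-working (unemployed, retired, other unemployed)
aged ≥ 25 ≥ 5,520 (2010 Active Solidarity Income); students and under-18s earn
0; non-working 18–24-year-olds have no floor.  Household income is the sum over
members.  Overweight/obesity (0 normal, 1 overweight, 2 obese) is drawn
independently per agent from a (gender, age band, SPC) contingency, falling back
to (gender, age band) and then to the overall marginal for missing strata (the
source survey covers adults only).

## Housing and allocation

Floors = max(1, ⌊height / 3 m⌋); a residential building is a house iff ≤ 2
floors and footprint < 250 m² (thresholds standing in for an unpublished
predictor; config keys), else a block.  Block dwelling count = round-half-up of
footprint × floors / average dwelling size, with ring averages 59 (center), 69
(inner), 89 m² (outer); recorded counts pass through untouched; houses hold one
dwelling.  Price classes are per-commune tertiles of price/m² (department
tertiles under 3 priced buildings; all-equal prices collapse to intermediate;
boundary values to the lower class).  Households are stratified into per-IRIS
income tertiles — tertiles, so the household partition aligns with the 3-class
dwelling partition — and allocated high stratum first, uniformly at random
within the matching class, spilling to the nearest class on saturation
(high→intermediate→low, low→intermediate→high, intermediate→high→low).  One
household per dwelling.

## The fixtures and what passing tests show

The ground-truth model draws every conditional cell from a Dirichlet mixed with
a uniform floor (no cell below ~2.5%), with structural zeros matching the hard
rules: heads and spouses of multi-person households live in the 35+ bands,
children in the 0–15 and 15–35 bands.  With the 15-year mother–child gap this
guarantees a child's feasible age window never empties and never excludes a
whole band, so band-level conditionals are sampled *exactly* and parameter
recovery is clean up to binomial noise.  The census emulator draws households
ancestrally from this tree (exact), attaches income and overweight, and is the
recovery oracle for the whole estimation-generation loop.

What passing tests therefore show: the estimator recovers the generating tree,
the generator reproduces it, conservation and structural validity are exact, and
the validation metrics behave as theory predicts (marginal SRMSE ~ n^(−1/2),
SRMSE increasing with joint complexity).  What they do not show: robustness to
real-census pathologies — informative missingness, heaped ages, inconsistent
sources across spatial levels, undercoverage — none of which the fixtures
emulate.

On statistical test calibration: the 50k-household recovery audit spans roughly
300 cell-category comparisons, so under a perfect estimator about 0.8 of them
are expected beyond 3 standard errors (and the chance of none is ~44%).  The
acceptance test therefore asserts the 3-SE band at its nominal family rate (at
most 1% of comparisons beyond 3 SE) plus a hard 4-SE cap; a biased estimator
fails both at once.  Thresholds follow from the binomial argument, not from any
observed run.

## Numerical and degenerate-input choices

Age bands [0–15), [15–35), [35–65), [65–120] are lower-inclusive,
upper-exclusive, last band upper-inclusive.  Probability vectors must sum to 1
within 1e-9.  Categorical draws use inverse-CDF on row cumsums (clipped at the
last index against roundoff).  Zero-probability rows after masking raise a
constraint error naming the entity; missing estimated cells raise an error
naming the cell.  All-zero observed distributions make SRMSE undefined (error);
zero variance makes R² undefined (reported, not raised).  Zero-population zones
produce zero households.

## Problem sizes

Default runs use 8 IRIS in 4 communes, 2 departments, 1 region; 10,000
households (~32,000 individuals) for the study-scale checks and 50,000
households for recovery, sizes at which binomial error bars are tight enough to
detect estimator bias while the full suite stays interactive on one CPU.

## Known limitations

- Conditional independences of the tree cap reproducible correlations (e.g.
  spousal education homogamy is not modelled).
- Income class (the car-ownership conditioner) is a categorical tree attribute,
  not derived from the EUR income assigned downstream; the two are consistent
  only in distribution.
- The Obepi-style contingency is applied to the population as-is (no temporal
  or regional adjustment), and overweight is conditionally independent of
  everything given (gender, age band, SPC).
- Multi-household dwellings, vacancy, temporal dynamics (aging, migration,
  household formation) are out of scope.
- Real-data ingestion is format-generic (delimited text, GeoJSON); national
  census file dialects require external conversion.
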