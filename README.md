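# gibbspop

Household-level synthetic population generation for agent-based urban and
environmental-health studies.

Activity-based exposure models need full agent populations — individuals with
coherent, jointly plausible socio-demographic profiles, grouped into households and
placed in dwellings — but census products only publish samples and aggregates.
`gibbspop` builds such a population from census-like microdata by **co-generating
all members of each household** from an explicit conditional probability tree,
using Gibbs sampling, then enriching agents with income and overweight/obesity
attributes and allocating households to geometry-derived dwellings by income.

## The model

Each individual is an attribute vector X = {X₁, …, Xₙ} (age band, gender,
socio-professional category SPC ∈ {1..8}, education, activity, …) nested in a
household (size ∈ {1..6}, type ∈ {Single, single parent, couple, family}, car
ownership).  The joint distribution is factorized along a tree of conditionals
estimated from microdata with a hierarchical spatial fallback (IRIS → commune →
department → region when a cell is sparse):

    P(size | zone), P(type | size), P(age | type, role), P(activity | age),
    P(SPC | age, activity), P(education | age, SPC), P(gender | role, type),
    P(income class | type), P(car | type, income class)

Generation per zone proceeds in four stages:

1. **Integerization** — the zone's population total N is decomposed into household
   counts h₁..h₆ with Σ s·hₛ = N exactly (±1 when infeasible), minimizing the
   deviation from the expected counts N·pₛ / Σ s′·pₛ′.
2. **Gibbs co-generation** — roles and genders are fixed structurally (member 1 is
   the head, the spouse takes the opposite gender, members 3+ are children); the
   free attributes are resampled from their full conditionals in a fixed sweep
   order (age → activity → SPC → education → car) under hard rules: heads are at
   least 21 (18 for one-person households), under-18s are schoolchildren with
   inactive SPC, retirees carry the retired SPC, mothers are at least 15 years
   older than their children.
3. **Enrichment** — income = α(SPC) × commune median × lognormal dispersion, with
   α(SPC) = median income of the SPC / population median, floored at the 2010
   minimum wage (12,672 €/yr, employed) and Active Solidarity Income (5,520 €/yr,
   non-working 25+); overweight/obesity (0/1/2) is drawn from a gender × age ×
   SPC contingency table.
4. **Housing** — buildings are classified house/block, dwelling counts derived
   from footprint × floors over ring-specific average dwelling sizes
   (59/69/89 m²), price-classed into per-commune tertiles, and households are
   matched to dwellings by income stratum with nearest-class spillover.

Validation is endogenous (66/33 train/test split at household level) with SRMSE
over marginals and up to 9-attribute joints, plus R²/RMSE/MAE on per-IRIS
occurrence percentages.

Because no public microdata can ship with the package, the `fixtures` module
generates all five inputs from a seeded ground-truth model, so every stage is
testable for parameter recovery against known truth.

## Worked example

```sh
cat > config.yaml <<EOF
seed: 1
n_households: 10000
EOF
gibbspop run-all --config config.yaml --out artifacts/
```

This emulates a 10,000-household census over 8 IRIS zones, estimates the
conditional tree from the 66% training split, Gibbs-generates a matching
synthetic population, assigns incomes and health status, builds the dwelling
stock and allocates households.  `artifacts/metrics.tsv` then contains, for
example (seed 1):

```
variables                                  scale   srmse
age_class                                  region  0.0257
gender                                     region  0.0076
spc                                        region  0.0271
MV4:age_class+gender+spc+main_activity     region  0.1960
MV9:age_class+...+household_size           region  5.2750
household_size                             iris    r2=0.956
```

Single-attribute SRMSEs near zero mean the synthetic marginals are statistically
indistinguishable from the held-out census split; SRMSE grows with the number of
jointly evaluated attributes (the cell grid explodes while the test support is
fixed), and per-IRIS R² close to 1 means the spatial heterogeneity of household
structure is reproduced, not just the regional aggregate.

The same artifacts can be produced stage by stage (`gibbspop fixtures`,
`preprocess`, `generate`, `housing`, `allocate`, `validate`) against one artifact
directory, and everything is reproducible byte-for-byte from the single `seed`.

## Layout

- `src/gibbspop/schema.py` — variable catalogue (bands, categories, roles)
- `src/gibbspop/preprocess.py` — cleaning, discretization, conditional estimation
- `src/gibbspop/generation.py` — integerization, Gibbs engine, structural rules
- `src/gibbspop/attributes.py` — income and overweight enrichment
- `src/gibbspop/housing.py`, `allocation.py` — dwelling stock and matching
- `src/gibbspop/validation.py` — SRMSE, fit metrics, joints, per-zone comparison
- `src/gibbspop/fixtures.py` — seeded ground-truth inputs for testing
- `docs/methods.md` — modelling assumptions, parameters and limitations
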