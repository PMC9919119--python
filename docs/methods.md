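# Methods

## The model

`herbisim` is a forward-time, individual-based simulator of two interacting
populations: hermaphroditic, diploid plants and dioecious, diploid
herbivores, both panmictic with discrete, synchronized generations and no
spatial structure, plasticity, or overlapping generations.

### Genetic architecture

Every *effect* trait — resistance, tolerance, and selfing in plants,
anti-resistance in herbivores — is controlled by two unlinked diallelic
genes. A genotype stores the effect-allele count (0/1/2) per gene; the
individual's *investment* in a trait is the carried fraction of the four
possible effect alleles, so investments take the values
{0, 0.25, 0.5, 0.75, 1}. Effect genes do not mutate: an allele lost from
expression can persist cryptically in heterozygotes and resurge later.

Plants additionally carry a load genome of 100 unlinked genes with two
allele slots each. An allele has (a) a neutral class (A/B), founded at
frequency 0.5 to provide standing heterozygosity, and (b) a detrimental
flag. Detrimental mutations arise one-way at rate `mu` per allele per
generation and are recessive-lethal: an individual homozygous for the flag
at any gene has fitness zero (culled at birth, which is distributionally
equivalent and cheaper). From this genome we derive the individual
heterozygosity `h_i` (fraction of the 100 genes whose two alleles differ
in composite class+flag state) and the detrimental-allele count `u_i`.

The neutral A/B classes are necessary: with only ~10 segregating lethals,
heterozygosity could never approach the outcrossing value of ~0.5 that the
overdominance term requires.

### Fitness

With `RC = c_r r^l`, `TC = c_t t^l`, `HD = c_h d^l`, `TB = b_t d^l t^l`,
`O1 = (h_i/H)^k`, `O2 = k (H − h_i)`, `D = (u_i s)^l`, and `I = 0` for
detrimental homozygotes:

- multiplicative: `F = (1−RC)(1−TC)(1−HD+TB) · O1 · (1−D) · I`
- additive: `F = (1 − RC − TC − HD + TB − O2 − D) · I`

Each parenthesized factor (and the additive sum) is floored at 0. `F` can
exceed 1 when `h_i > H` (multiplicative) or via `O2 < 0` (additive). The
additive overdominance term is implemented as a *penalty* for
below-reference heterozygosity, which is the stated intent of the model;
the opposite sign convention is available behind `o2_sign_verbatim`.

Tolerance is strictly inducible: `TB` carries the damage factor `d^l`, so
benefit without damage is impossible. Damage is binary (resistance is
all-or-nothing, herbivory cost constant).

Realized seed numbers are Poisson with mean `w0 · F`. Thinning a
Poisson(`w0`) base by the factor `F` gives exactly Poisson(`w0 F`), and the
same form extends naturally to `F > 1`.

### Herbivory (gene-for-gene)

Each herbivore attacks one plant per generation, chosen uniformly with
replacement. Per gene, ≥1 resistance allele arms the plant; ≥1
anti-resistance allele at the matching gene disarms it; the attack succeeds
iff no armed gene remains un-disarmed. Plants without resistance alleles
are fully susceptible. Herbivore fitness is
`(1 − c_a a^l)(1 − failure_cost (1 − fed))`, floored at 0. The cost of a
failed attack is a configurable fitness proportion (default 0.75, mirroring
the herbivory cost) rather than death, so herbivore populations are not
trivially extirpated; only the anti-resistance cost `c_a` is part of the
core parameterization.

### Reproduction and mating system

Each plant mothers Poisson(`w0 F`) seeds. A seed selfs with the mother's
selfing probability, otherwise its pollen parent is drawn uniformly from
all plants (pollen production is not fitness-weighted, and selfers donate
pollen unless `selfers_donate_pollen = false`). Two selfing modes:

- **heritable** — selfing probability equals the selfing-allele dosage
  (count/4); selfing genes keep their transmission ("automatic") advantage
  through pollen export, which is why they behave as selfish genes.
- **non-heritable** — a binary selfer tag transmitted maternally and never
  through pollen; tagged plants self all ovules. Removing the pollen
  pathway is precisely what separates the two modes' outcomes.

Offspring are built gamete by gamete: independent Mendelian segregation at
every gene (free recombination), detrimental mutation of load-genome
alleles, fusion, and culling of detrimental homozygotes. Survivors are
subsampled uniformly to `K_plants`; populations may shrink below capacity,
which allows inbreeding-driven extinction. Herbivore females produce
Poisson(`fecundity · F_h`) offspring, sires are drawn among males weighted
by `F_h`, offspring sex is equiprobable, and the population is regulated to
`K_herbivores`.

Generation-event order is fixed: attacks → plant fitness/reproduction →
herbivore reproduction → record. Damage precedes reproduction so tolerance
benefits act within the generation that incurs them. Herbivore extinction
does not halt a run (plants continue damage-free); plant extinction ends it
with a terminal status.

## Parameters

Model defaults: `w0 = 25`, `c_r = 0.15`, `c_t = 0.4`, `c_h = 0.75`,
`b_t = 0.25`, `c_a = 0.4`, `k = 0.3`, `H = 0.25`, `s = 0.005`, `l = 1`
(allowed 0.2–5). All costs/benefits are proportions of fitness.

**Mutation rate.** The per-allele rate defaults to `mu = 0.00245`, i.e. a
diploid genomic rate `U = 2·100·mu = 0.49`. This value is pinned by the two
load equilibria the model predicts: under full selfing every new lethal is
exposed and purged within about a generation, so the standing load is
`U ≈ 0.49`; under random mating, mutation–selection balance for lethal
recessives gives `q* = sqrt(mu)` per gene (the fixpoint of the exact
recursion `q' = q/(1+q) + mu(1 − q/(1+q))`), hence `2·n·sqrt(mu) ≈ 9.9`
alleles per zygote. The theory module exposes both closed forms, and the
recursion fixpoint is verified in the test suite.

**Structural defaults** (not part of the core model; config-exposed):
plant and herbivore carrying capacities 500, initial effect-allele
frequencies 0.5 (both alleles common at the outset), initial neutral-class
frequency 0.5, initial selfer-tag fraction 0.5, herbivore fecundity 25 and
failure cost 0.75, horizon 15,000 generations, 3 replicates.

**RNG contract.** One `numpy` PCG64 stream per replicate, seeded from
`SeedSequence([seed, replicate])` (`[seed, cell, replicate]` in sweeps).
Equal `Params` (including seed) give byte-identical outputs.

## Theory companion

`theory.scenario_predictions` evaluates the resistance vs. non-resistance
fitness maxima at `l = 1`, `d = 1`: `w_RS = 1 − c_r r*^l` with `r* = 0.25`
(one retained allele — the minimum investment that still protects, and the
reason selfing carries a hidden *resistance cost*: homozygotes carry
redundant resistance alleles); `w_NRS` as the exact product
`(1 − c_t t_h)(1 − c_h + b_t t_h)` at the closed-form optimum
`t_h = ½(1/c_t − (1−c_h)/b_t)` clipped to [0, 1] (multiplicative), or the
corner optimum `t ∈ {0, 1}` by the sign of `b_t − c_t` (additive). A
linearized variant of `w_NRS` is exposed alongside for comparison, but the
exact product is authoritative: it is the function whose maximizer is
`t_h`. The ratio `f_r = w_NRS/w_RS` decides the favored scenario.
`curvature_class` maps the sign of a powered term and the exponent `l` to
convex/concave/linear. `fitness_surface_grid` emits long-format tables of
`F` over any two of {c_r, c_t (with `b_t = 1 − c_t`), r, t, d, l};
rendering is left to the caller.

## Summaries

*Persistence* of a trait is its allele frequency averaged over all
generations and replicates; runs that ended early are padded with their
terminal frequency so cells remain comparable. Outcomes are classified
from the mean frequency in the final 10% of generations: fixed (> 0.95),
lost (< 0.05), else polymorphic; mixed defense = resistance and tolerance
both present, mixed mating = selfing polymorphic. The thresholds and
window are arguments with these defaults, chosen as conventional
fixation/loss cutoffs; no numeric zone criteria are inherited from
elsewhere.

## Numerical choices

- **Seed-pool capping.** Only a uniform random subsample of 4 × `K_plants`
  seed slots is instantiated per generation: subsampling slots before the
  lethality cull commutes with subsampling survivors after it, so the
  result is distributionally identical to building every seed. If the
  capped pool cannot fill the capacity (possible under extreme lethality,
  e.g. the purge phase after selfing fixes), the full pool is built
  instead.
- `0^0 = 1` (numpy convention), so `k = 0` or `l` applied to zero bases
  neutralizes the corresponding terms.
- Heterozygosity is reported as the fraction of the 100 load genes that
  are heterozygous (definitional range 0–1); 0 and 0.5 emerge as the
  realized limits under selfing and outcrossing respectively.
- Ties and degenerate inputs: empty herbivore populations yield zero
  damage and NaN attack rates; a plant population below 2 viable seeds is
  an extinction, recorded as a terminal status rather than an exception.

## What the generator emulates — and what it does not

Initial populations are founded in linkage equilibrium at the configured
allele frequencies with a clean load genome; the first few hundred
generations therefore include a transient in which the load climbs to its
balance value (analyses here discard a burn-in or average a final window).
Real populations differ in ways the model deliberately omits: polygenic
and plastic selfing, partial resistance, non-lethal deleterious mutations
of variable effect, linkage, spatial structure, and pollinator dynamics.
Passing tests show the model's internal consistency with its own
equilibria, not calibration to any empirical system.

## Problem sizes used in the checks

The bundled checks run the full model at desk scale, chosen to keep the
statistics stable: the acceptance script uses 500–1,000 plants, 500
herbivores, 1,000–2,000 generations, 3 replicates per quantity; the test
suite uses 200–1,000 individuals and 500–1,500 generations (the
tolerance-boundary sweep uses 9 grid points × 3 replicates at 200/200
individuals and 500 generations). Equilibria in this model are reached
within a few hundred generations, so these horizons sit safely past the
transient; the full 15,000-generation, 2,000-run experimental design
remains available through `run_sweep`.

## Known limitations

- The non-heritable selfer tag is strictly maternal; other inheritance
  conventions for tagged lineages (e.g. paternal leakage) are not modeled.
- Herbivore density dependence is a hard ceiling; no functional response.
- The additive model's fitness floor at 0 makes strong-cost regions
  insensitive to further cost increases.
- The overdominance selfing equilibrium (an interior `h_i` balance point
  under selfing) has no closed form in the theory module; only the
  dominance (lethal-recessive) equilibria are predicted analytically.
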