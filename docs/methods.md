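# Methods

## Model

`deafsim` is a forward-in-time, individual-based model of a single autosomal
locus at which a recessive allele *a* causes congenital deafness
(a DFNB1A/GJB2-like trait). The population is closed: no migration, no de
novo mutation, non-overlapping generations (one cycle = one generation,
nominally 20 years). Each agent carries:

- sex (male/female, Bernoulli 1/2),
- two binary alleles (genotype; *aa* = genetically deaf),
- an environmental-deafness flag (Bernoulli `prop_env_deaf`, independent of
  genotype, applied to every newborn and at initialization),
- phenotype `deaf = genetic_deaf OR env_deaf`,
- a sign-language flag, drawn at birth with probability `prop_sign_deaf`
  (deaf) or `prop_sign_hearing` (hearing),
- a social-position threshold (a scalar, default 0 for all agents).

One generation proceeds as: couple formation → offspring generation →
wholesale replacement of the parental population by the children.

### Couple formation

Every potential male × female pair receives a mutual-evaluation score

- both hearing: `2·W_P^H`
- both deaf, both signing: `2·(W_P^D + W_S^D)`
- both deaf otherwise: `2·W_P^D`
- deaf × hearing, both signing: `W_S^H + W_S^D`
- otherwise: 0.

A pair is eligible when its score strictly exceeds both candidates'
social-position thresholds, i.e. `S > max(sp_i, sp_j)`. Two published
variants of this rule family exist; switches are provided
(`mixed_rule="equation"` scores the mixed branch as `W_P^D + W_S^D`;
`threshold_rule="min"` uses the laxer threshold). With the bundled presets
the variants are dynamically indistinguishable, because mixed-pair scores
are only ever compared against zero or tie with the top score.

Couples form greedily: repeatedly pick a uniformly random pair among the
eligible pairs attaining the current maximum score, marry it, remove both
agents. `form_couples_matrix` implements this literally on the dense score
matrix (used as the oracle on small populations, and as the fallback when
per-agent social positions differ). `form_couples_fast` exploits that the
score depends only on each partner's (deaf, signs) class: agents within a
class are exchangeable, so the greedy process collapses to a class-level
process over at most 4 × 4 score blocks, handled per descending score level:

- a level whose blocks form a complete bipartite product over its classes is
  matched by pooled uniform matching (multivariate-hypergeometric class
  allocation of the `min(males, females)` matched agents per side);
- any other level runs the exact sequential urn process: each step selects a
  block with probability proportional to the product of its remaining class
  sizes (the number of remaining eligible cells), and removes one agent per
  side.

This is distribution-identical to the matrix matcher, and a chi-square
equivalence test over repeated paired trials on small mixed populations
enforces it in the test suite. Complexity is near-linear in population
size; the urn loop only runs on deaf-involving levels, whose pools are a
fraction of a percent of the population.

### Reproduction

Each couple is classed DD/DH/HH by the partners' deaf phenotypes and draws
its number of children as `c_max · Beta(α, β)` with `α + β = ν`
(concentration) and mean equal to the class birthrate, stochastically
rounded (floor plus a Bernoulli on the fractional part) so the expected
integer count equals the configured birthrate exactly. The reference
birthrates are 1.78 (DD), 1.70 (DH) and 2.24 (HH) children per couple —
the 22% fertility reduction of deaf couples — with equal rates encoding
neutral selection. The published description does not fix the shape
parameters; defaults `c_max = 10`, `ν = 4` are used, and because the
trajectories depend on the means (guaranteed exact), not the shape, the
shape is exposed only for robustness checks.

Children inherit one uniformly chosen allele from each parent. Unmatched
agents leave no descendants. Zero couples or zero total children is
extinction: statistics report it explicitly rather than dividing by zero,
and a batch records extinct replicates without failing.

### Initialization

Genotype counts are deterministic rounded targets (`round(N·prop_hom)`
homozygotes, `round(N·prop_het)` carriers) assigned in random order, so the
generation-0 allele frequency is exact — e.g. the reference composition
(0.25% *aa*, 10% carriers) gives q₀ = 5.25% exactly. The reference
composition is deliberately *not* Hardy–Weinberg at the observed carrier
rate: it is the only composition consistent simultaneously with the
reported initial homozygote proportion (0.25%), initial allele frequency
(5.25%), and the first-generation random-mating homozygote value
(≈ q₀² = 0.276%). Environmental deafness is applied independently of
genotype (including to homozygotes, where it is unobservable).

## Scenario presets

- **no_deaf_mating** (purifying selection): nobody signs and `W_P^D = 0`,
  so every deaf-involving pair scores 0 and fails the strict threshold;
  deaf agents never marry. Expected allele-frequency dynamics follow the
  zero-fitness-recessive recursion `q ← q/(1+q)` (see Oracles).
- **assortative** (relaxed selection): all deaf sign; a small calibrated
  fraction κ of hearing agents signs; weights `W_P^H = 1, W_P^D = 1,
  W_S^D = 1, W_S^H = 3` make deaf × deaf and deaf × hearing-signer tie at
  the top score (4) above hearing × hearing (2). The greedy tie-break then
  dilutes deaf–deaf pairing: the realized assortment (fraction of married
  deaf whose spouse is deaf) is set by the ratio of the signing-hearing
  pool K to the deaf pool D. In the fluid limit of the urn process
  `ln K − D/K` is invariant, giving `K·(1 − e^(−D/K)) = (1 − r)·D` for a
  target assortment r; solving for the Yakut-like composition
  (D ≈ 0.4994% of N, r = 0.771) and refining against the simulated matcher
  at N = 20,000 gives κ = 0.00122 (realized 0.7703 ± 0.0016). The realized
  rate drifts mildly (≈ 0.77 → 0.80) as the deaf pool swells near the
  homozygote peak, since κ is a fixed population property.
- **random_mating** (neutral selection): scoring bypassed, uniform random
  pairing, all birthrates 2.24 (equal fitness regardless of genotype).
- **usa_validation**: 0.2% homozygotes; environmental deafness 0.8% so
  homozygotes are 20% of the deaf at initialization; all deaf sign;
  κ = 0.002536 calibrated to 76% assortment; equal fitness at 2.1 children;
  10 generations; 95% CIs. The carrier proportion is not published for this
  setting. A Hardy–Weinberg-consistent 8.5% provably caps the assortative
  homozygote excess near 0.26% in this model (mean-field recursion below),
  short of the documented ≈ 1.9× rise; the carrier rate a mean-field
  treatment needs to reach that rise is ≈ 10% (q₀ ≈ 5.2%), which is adopted
  as the reconstruction. With it the simulated prevalence rises ≈ 1.6×
  (0.2% → 0.33%), inside the empirically reported 1.5–2.4× range.
- **yakut_census**: demographic check only — 227,384 founders, no mutant
  alleles, uniform birthrate 2.24, five generations; final size is compared
  with the 2010 census count (466,492) at ±20%.

The mean-field recursion used for the USA analysis: with homozygote
fraction h, environmental-deaf fraction e and assortment r, the extra
homozygotes per generation from deaf × deaf unions are ≈ r·h²/(h+e)
(both-partners-*aa* unions produce only *aa* children), on top of the
random-mating background q²; equilibria follow by iterating
`h ← q² + r·h²/(h+e) + (carrier-union terms)`.

## Statistics

Each replicate logs, per generation: population size, deaf count,
homozygote count and proportion, recessive allele frequency, couples
formed, and realized assortment. Batches derive per-replicate generators
from a root seed via `SeedSequence(root, spawn_key=(i,))` (any replicate is
re-runnable in isolation) and summarize each statistic as mean ±
`z(level)·sd/√n` (normal-approximation CI, z at the 0.995/0.975 quantile
for 99%/95%), matching the symmetric ± values of the reference trajectories.
Runs are exactly reproducible: one generator per replicate feeds every
stochastic draw in a documented order.

## Oracles

Closed-form references (in `deafsim.oracles`) used by the test suite and
exported for users: the zero-fitness recessive recursion
`q_t = q₀/(1 + t·q₀)` (validated against an independent genotype-class
bookkeeping recursion to 10⁻¹²), the Hardy–Weinberg homozygote proportion
q², and the random-mating probability h² that both spouses are homozygous.
Note the recursion assumes Hardy–Weinberg genotype proportions; the
non-Hardy–Weinberg start shifts the purifying-selection endpoint by ≈ +0.01
percentage points (q₂₀ ≈ 2.567% instead of 2.561%), visible in the
reference endpoint 2.57%.

## Problem sizes and numerical choices

Full-scale experiments (N = 200,000, 1000 replicates) are supported
(`--full`), but the documented workflow runs reduced, scale-invariant
batches: the bundled acceptance script uses N = 10,000 × 300 replicates for
the three Yakut scenarios and N = 20,000 × 200 for the USA check; the test
suite uses N = 4,000–6,000 × 200. Batch initial sizes are chosen so
`round(N·prop_hom)` is exact (multiples of 2,000 for the 0.25%
composition). Residual finite-size effects are O(1/√N): sex-imbalance
leftovers in the marriage market (genotype-neutral) and drift-curvature
bias in mean trajectories (≲ 10⁻⁴ in allele frequency at the sizes used);
test tolerances carry small absolute allowances for these on top of
replicate CIs.

## What the generator does and does not emulate

The synthetic populations encode the study conditions (initial genotype and
phenotype composition, sign-language prevalence, couple-class fertility);
they do not model age structure, mortality before reproduction, migration,
polygyny/remarriage, multiple deafness loci or heterogeneous hearing-loss
etiologies, de novo mutation, or heterogeneous social positions (supported
by the data model and the matrix matcher, but no distribution is published
to emulate). Passing tests therefore validate the mating/selection
machinery under these idealized conditions, not demographic realism of any
actual population.

## Known limitations

- The realized assortment rate is an emergent, calibrated property of the
  tie-break mechanism, constant-κ across generations; alternative published
  mechanisms (unavailable in detail) might hold it exactly fixed.
- The USA carrier proportion is a reconstruction (see above); the USA
  endpoint is accordingly a structural estimate, ~15% below the reference
  print.
- Under strictly equal fitness the allele-frequency martingale keeps the
  random-mating trajectory at 5.25% in expectation; the reference
  trajectory prints 5.23% from generation 2 (unexplained by equal fitness;
  difference 0.4% relative).
- The matrix matcher is O(M·F) memory and is only intended for populations
  of a few thousand agents.
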