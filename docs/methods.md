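# Methods

## Model

Individuals are points in an *n*-dimensional trait space; fitness is
Gaussian in the distance to a fixed optimum at the origin,
*w*(*z*) = exp(−Σ *z*ᵢ²). Generations are discrete and non-overlapping
with constant population size *N* (Wright–Fisher): the offspring
generation is one multinomial draw of *N* individuals with class
probabilities proportional to parental count × fitness, after which a
Poisson(*N·U*) number of de novo mutations is assigned to uniformly
random newborns. Assigning a pooled Poisson(*N·U*) total to uniform
individuals is distributionally identical to independent Poisson(*U*)
draws per individual (Poisson thinning), and naturally allows one
newborn to carry two or more new mutations.

A mutation picks *m* distinct traits uniformly without replacement and
adds an independent Normal(0, σ²) deviate to each (additive action on
trait values, the standard FGM convention). There is no back mutation,
recombination, epistasis beyond what the geometry induces, environmental
change, or frequency-dependent selection. Mutations are unique lineage
events (infinite-sites at the lineage level).

Order of events within a generation: resampling (selection + drift)
first, then mutation in the newborns, then the census. Newborn mutation
is the conventional choice and makes the Poisson(*N·U*) input exact; the
census therefore sees the population that begins the next generation.

## Parameters

| name | meaning | units | default |
|---|---|---|---|
| `n` | traits under selection (complexity) | – | required |
| `m` | traits altered per mutation (pleiotropy), 1 ≤ m ≤ n | – | required |
| `sigma2` | per-trait mutational variance σ² | squared trait units | required (or `E_S`) |
| `E_S` | mean effect of a random mutation at the optimum; sets σ² = \|E(S)\|/m | – | alternative to `sigma2` |
| `U` | genomic mutation rate | per individual per generation | required |
| `N` | population size | individuals | required |
| `w0` | founder fitness | – | 0.5 |
| `record_every` | trajectory/mean-fitness cadence | generations | 1 |
| `placement` | founder position rule | – | `random_direction` |

`E_S` uses the first-order relation E(S) = −*m*σ² exactly for the
conversion; the exact mean multiplicative fitness factor at the optimum,
(1 + 2σ²)^(−m/2), is exposed as `exact_mean_fitness_factor` and agrees
with the first-order value to within 1% for the σ² ranges of interest
(σ² ≲ 0.07). Exactly one of `sigma2`/`E_S` may be configured.

## Founder placement

The founder is monomorphic at fitness `w0`, i.e. at distance
d = √ln(1/w0) from the optimum. Where on that shell matters only under
partial pleiotropy: with *m* = *n* every direction is statistically
equivalent (the mutation distribution is isotropic), but with *m* ≪ *n*
the axis position — all displacement on one trait — is a degenerate
geometry in which only the fraction *m*/*n* of mutations that hit that
trait can be strongly selected. The default is therefore
`random_direction`, the generic position in trait space, which spreads
the displacement over all coordinates; the deterministic `axis` placement
is kept as an option. At *n* = 500, *m* = 3 this choice is what produces
the slow adaptation and first-fixation waiting times beyond 2,000
generations that characterise high-dimensional landscapes; the axis
placement roughly halves those waiting times by concentrating the
adaptive challenge in a single trait.

## Genotype-class representation

The population is a table of classes — distinct sets of segregating
mutation ids with a shared phenotype, cached log-fitness and a count —
so per-generation cost scales with the number of distinct genotypes.
Selection probabilities are computed from log-fitness with max-shift
before exponentiation, so genotypes arbitrarily far from the optimum
cannot underflow the weight vector. Classes drawn to count 0 are dropped
immediately. A naive per-individual engine (`reference_step`:
fitness-weighted parent choice per offspring, per-individual Poisson(U)
mutation) implements the same model without aggregation; the test suite
checks distributional agreement of the two engines on small instances,
both for the resampling distribution of a selected lineage and for mean
fitness after 50 generations with mutation.

## Fixation, loss and cohorts

The census after each generation counts carriers of every segregating
mutation. Fixation is carrier count exactly *N* at a census; loss is
count 0; both are absorbing (no back mutation). All mutations first
reaching count *N* at the same census form one fixation event — the
cohort — and cohort membership is defined only by this simultaneous
first arrival at frequency 1, the operational definition behind the
quantitative summaries. Events in adjacent generations are not merged.
Fixed mutations are pruned from the class sets into a fixed background
(phenotypes already contain their effect, so mean fitness is unchanged;
the tests assert this). Frequency trajectories are recorded on the
`record_every` grid; a fixation census is always recorded regardless of
cadence, and each lost mutation gets an explicit final 0.0 record, so no
fate is silent in the output tables. Runs aggregated across replicates
must share all parameters; replicates without any fixation are reported
in a separate bin of the cohort-size distribution, never dropped.

## Observation noise

`add_observation_noise` perturbs recorded frequencies by iid
Normal(0, variance) draws (default variance 0.02, mimicking the
measurement error of sequencing-based frequency estimates) and clips to
[0, 1], since frequencies outside the unit interval are unphysical. The
noise is applied only to the exported `trajectories_noisy` table and is
never fed back into the simulation.

## Reproducibility

Replicate *r* uses the child seed
`numpy.random.SeedSequence(master_seed, spawn_key=(r,))`; the noisy
trajectory table uses `spawn_key=(r, 1)`. The manifest records the
scheme, the master seed and the full parameter set; identical configs
reproduce byte-identical tables (floats are written at 17 significant
digits and read back with round-trip parsing).

## Test and acceptance scales

Full-size experiments in this regime are 100-replicate, 30,000-generation
runs at *N* = 10⁴–10⁵; the package's own checks run the same model at
desk scale. The acceptance computation uses 11 replicates at *n* = 500,
*m* = 3, *N* = 10⁴, each run only until its first fixation (horizon
30,000 generations; a run without fixation contributes its horizon as a
lower bound on the waiting time). The trend checks use *N* = 2000 with
*n* = *m* = 3, 20 replicates per condition, and contrast U = 0.01 vs
0.0005 and E(S) = −0.001 vs −0.2 for first-fixation cohorts, and
E(S) = −0.1 vs −0.003 along 6,000-generation walks for the decline of
cohort sizes. At these scales the qualitative orderings are stable
across seeds, but absolute cohort sizes are smaller than at *N* = 10⁴ —
clonal interference weakens with *N·U* — so the synthetic checks
demonstrate the orderings and the machinery, not the full-scale
distributions.

## Limitations

* Asexual, fixed optimum, isotropic Gaussian fitness; no recombination,
  demography, mutators, ecology or frequency dependence. Comparisons to
  experimental populations where those forces act are out of scope.
* Cohorts are defined by simultaneous co-fixation, not inferred by
  clustering co-moving frequency trajectories as done for experimental
  data; the noisy trajectory table exists precisely so users can apply
  such inference downstream.
* Memory grows with the number of mutations ever created (the registry
  keeps every record for the output tables); at *N·U* ≫ 1 over very long
  horizons this is the dominant footprint.
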