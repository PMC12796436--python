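# Methods

`soilfoodweb` reconstructs weighted trophic networks for soil
invertebrate communities (nematode microfauna through earthworm
macrofauna) and estimates the energy flux through every feeding link
under a steady-state balance. This note documents the model, its
assumptions, the defaults, and the design choices made where the method
leaves room.

## Food-web reconstruction

A site's web has 7 basal resource nodes — algae (A), living plants (P),
bacteria (B), fungi (F), leaf litter (L), deadwood (W) and soil organic
matter (S) — plus one node per consumer guild. The diet matrix
`W` is column-stochastic: `W[i, j]` is the share of node `i` in consumer
`j`'s diet, and each consumer column sums to one.

Link plausibility is the product of independently scaled [0, 1] factors:

1. **Feeding preference** — graded trait weights over the 7 resources
   plus an `animal` weight for predation.
2. **Body-mass niche** — guild body masses are log10-normal with SD
   σ = 1 decade. A predator of mean log-mass μ_pred has an optimum-prey
   distribution centred at μ_pred − log10(R*) with the optimum
   predator–prey mass ratio R* = 100. The factor is the overlap
   coefficient of two equal-variance normals,
   `2·Φ(−d / 2σ)` with `d = |μ_prey − (μ_pred − log10 R*)|`.
   The overlap metric is our operationalisation of "body-mass
   distribution overlap"; the closed form makes it cheap and exactly
   testable.
3. **Spatial niche** — habitat weight vectors over
   {soil, litter, ground, aboveground} summing to one; the factor is the
   sum of stratum-wise minima, so a strictly ground-dwelling predator
   and a strictly endogeic earthworm never interact.
4. **Biomass dependence** — encounter rates favour locally abundant
   prey: prey biomass divided by the maximum biomass over the predator's
   feasible prey (keeping the factor in [0, 1]).
5. **Protection** — the prey's protection multiplier in [0, 1]
   (1 = unprotected), straight from the trait table.
6. **Isotopic plausibility** — the prey signature (δ15N, δ13C) is
   shifted by one trophic enrichment step (+3.4 ‰, +0.4 ‰) and compared
   with the predator's; the factor is a Gaussian kernel
   `exp(−D²/2b²)` of the Euclidean distance D with bandwidth
   b = 3.4 ‰ (one enrichment step). Any missing isotope value makes the
   factor a neutral 1. The kernel form and bandwidth are our choices
   (both configurable); only the enrichment factors are fixed by the
   method.

Stable isotopes also refine the preference *budget* before the factors
are applied, all linear with clamping:

* **Algivory**: algal diet fraction = (2.0 − δ15N) / (2.0 − (−1.4)),
  from 0 at the 2 ‰ threshold to 1 at the observed minimum of −1.4 ‰.
  Applied only to guilds whose trait table grants a nonzero algal
  preference — without that guard, any low-δ15N strict predator would
  acquire algivory out of nothing.
* **Earthworm litter/soil split**: soil fraction of the detrital (L+S)
  preference mass = (δ15N − 1.2) / (5.5 − 1.2), i.e. epigeic
  litter-feeders at the low end, endogeic soil-feeders at the high end.
* **Omnivore predation**: animal share = position of the omnivore's
  δ15N between the web-wide minimum and maximum; a degenerate web
  (max = min) falls back to 0.5 with a warning.

After the refinements, each consumer column allocates the basal and
animal blocks proportionally to the refined preference budget and is
normalised to sum one. A consumer whose column is all zero, or a
predator with animal preference but no feasible prey, is a hard
reconstruction error naming the guild.

The **omnivory parameter** ω used in the sensitivity sweep sets every
*originally nonzero* auxiliary preference (everything except the
guild's maximum-preference resource) to ω times the main preference;
zero preferences never become links. The sweep runs the full pipeline
on the 11-point grid ω = 0.0, 0.1, …, 1.0; the default configuration
(`"as-given"`) skips the override entirely and reproduces the baseline.

## Energetics

Individual metabolic rate follows the Arrhenius-corrected allometry
`ln I = ln b0 + a·ln M − E/(kT)` with I in J h⁻¹, M fresh mass in mg,
T in kelvin, k = 8.617×10⁻⁵ eV K⁻¹. The shipped default coefficients
(ln b0 = 23.055, a = 0.695, E = 0.686 eV) are the cross-group
invertebrate regression of Ehnes et al. (2011); `coefficients.yaml` is
user-editable per phylogenetic group and carries provenance fields.
Rates convert to mW by 1/3.6. Guild-level demand is
`X = (biomass × 1000 / mass) × I_individual` (mW m⁻²) at the site's
mean annual temperature (taiga 5.2, mixed broadleaved 7.1, beech 7.5,
rainforest 25.2, monsoon 26.0 °C).

Assimilation efficiencies are prey-specific: plants 0.21, litter 0.18,
soil organic matter 0.13, bacteria 0.96, fungi 0.36 (algae and deadwood
default to the fungal and litter values and are configurable). Animal
prey scale linearly with tissue N% from 0.50 at 5 % N to 0.99 at 12 % N,
clipped; this linear placeholder stands behind a single function and is
trivially swappable for a published N-content equation. Missing N%
falls back to the bound midpoint with a warning.

Body length → fresh mass uses per-taxon power laws
`log10(mass mg) = a + b·log10(length mm)`; shipped values are
illustrative and user-editable.

## Steady-state flux balance

With ē_j = Σ_i e_i·W_ij the diet-weighted mean efficiency, each
consumer satisfies "losses = gains":

    ē_j · F_j = X_j + Σ_k W_jk · F_k

solved exactly as the linear system `(diag(ē) − C) F = X`, C being the
consumer-row block of W. Link fluxes are `L_ij = W_ij·F_j`; the total
energy flux is Σ_j F_j = Σ L (making the trophic-function percentages an
exact partition). Basal resources are unlimited sources. A singular
system is reported as structurally infeasible; any negative intake as
energetically infeasible with the offending guilds named — never
silently clamped. Per-consumer balance residuals are recomputed
independently after every solve (`check_balance`) and are below
10⁻⁹·max(X) on all fixtures, including mutual-predation loops.

Trophic levels take basal resources as level 1 and
`TL_j = 1 + Σ_i W_ij·TL_i`, solved as a linear system so omnivory loops
are handled exactly.

## Summaries

* **Trophic functions**: outgoing flux summed by source class —
  herbivory (P), algivory (A), bacterivory (B), fungivory (F), litter
  (L), deadwood (W) and soil (S) consumption, and predation (all
  invertebrate sources). Each link source is exactly one class, so the
  eight absolute values sum to the total flux and percentages to 100.
* **Fungivory:bacterivory ratio** of absolute fluxes; zero bacterivory
  is flagged undefined rather than returned as infinity.
* **Body-mass spectrum**: five half-open bins of fresh body mass with
  the conventional printed edges 0.05–1.6 µg, 1.6–50 µg, 0.05–1.6 mg,
  1.6–50 mg, 0.05–1.6 g. These printed edges are decimal roundings of
  exact 1.5-decade bins, so their geometric midpoints are spaced exactly
  1.5 decades. Per-bin sums of biomass and of node intake F (intake was
  chosen over outgoing flux; a node's outgoing flux double-counts
  energy already attributed to its consumers). The slope is OLS of
  log10(bin sum) on log10(geometric midpoint) over bins 1–4 only — the
  largest class is excluded as undersampling-prone; zero bins are
  dropped with a warning and fewer than three usable bins is an error.
  Out-of-range masses are clamped into the end bins with a warning.
* **Unit conversions**: flux (mW m⁻²) → fresh biomass consumption
  (g m⁻² y⁻¹) via an energy density of 7×10⁶ J per kg fresh biomass and
  a 365-day year (31,536,000 s; the share reproductions depend on the
  year-length convention only at the second decimal). NPP share =
  converted flux / NPP × 100, reported to the nearest integer percent.
* **Seasonal-bias utility**: the mean of a monthly biomass series
  expressed as % of a reference month, for judging snapshot sampling in
  seasonal forests.

## Synthetic-site generator

The generator emulates the study conditions so the pipeline is testable
without field data:

* Total fresh biomass per site is drawn from a normal truncated at
  zero, with SD from the per-forest biomass table (taiga 7.8 ± 3.3,
  mixed broadleaved 17.1 ± 8.7, beech 26.9 ± 11.5, monsoon 50.4 ± 25.1,
  rainforest 6.6 ± 3.1 g m⁻²). Because truncation at zero shifts the
  mean of a naively parameterised truncated normal upward (by up to
  +1.4 g m⁻² for monsoon), the location parameter is solved numerically
  so the *truncated distribution's mean equals the tabulated mean*
  exactly.
* The litter/soil split follows the tabulated per-forest layer means
  and is applied uniformly across guilds (per-guild layer affinity is
  not modelled).
* 12–20 guilds are drawn per site from a 23-guild pool spanning all
  five body-mass classes; biomass shares are Dirichlet draws around
  per-forest base shares. Tropical presets are macrofauna-dominated
  (termites and large herbivores occur only there); in mixed broadleaved
  forests the two earthworm guilds receive a uniformly drawn 91–96.5 %
  of total biomass, so every site is earthworm-dominated (> 90 %).
* Body masses are log-normal around guild-specific centres (SD 0.3
  decades), clamped to the guild's size-class compartment.
* Isotopes: δ15N = 3.4 ‰ × (intended trophic level − 1) and
  δ13C = 0.4 ‰ × (TL − 1) over a 0 ‰ litter-calibrated baseline, with
  Gaussian noise (SD 0.5 ‰). Earthworms and the partially algivorous
  springtail guild carry explicit δ15N centres so the isotope
  refinements are exercised across their ranges.
* All randomness flows through one `numpy.random.default_rng` seeded
  from the (seed, forest-type index) pair; outputs are bit-reproducible.

What it does **not** emulate: spatial autocorrelation among sites,
seasonal dynamics, realistic per-guild isotope variances or covariances,
taxonomic richness (32 field guilds vs the 23-guild pool), and absolute
flux magnitudes (these depend on the placeholder metabolic
coefficients). Passing tests therefore demonstrate correctness of the
reconstruction/flux machinery and the generator's calibrated biomass
structure — not quantitative agreement with field fluxes.

## Numerical choices and degenerate inputs

* Diet columns are validated to sum to 1 ± 10⁻⁹; the solver uses LAPACK
  `solve` (no iteration), with negative intakes below
  10⁻¹²·max(X) treated as zero.
* Half-open mass bins `[lo, hi)`: a mass exactly on an edge belongs to
  the upper bin.
* Guilds missing isotope rows are flagged at merge time and receive
  neutral isotope weights; their refinements are skipped with a WARN
  log.
* Community tables may give biomass directly or density × mass (or
  length via the allometry table); per-layer rows are summed and the
  guild mean mass is the biomass-weighted mean of layer masses.
* Problem sizes in the shipped analyses: 4 sites per forest type for
  the end-to-end drivers, 200 seeds per type for the generator
  calibration check, 100 random webs (≤ 8 nodes) for the solver oracle
  comparison — small enough to run in seconds while exercising every
  branch.

## Known limitations

* Metabolic, allometric and animal-efficiency coefficients are
  editable placeholders; absolute fluxes are only as good as the
  supplied coefficient tables.
* The exact functional forms of the body-mass overlap, biomass scaling
  and isotope kernel used in the original R workflow are not published
  in closed form; ours are explicit, configurable and independently
  tested, but not guaranteed to match that script numerically.
* One web per site (layers summed before reconstruction); per-layer
  webs and seasonal re-weighting are out of scope.
* No dynamic simulation, stability analysis, or inferential statistics
  (mixed models, ordinations) — the package stops at the solved webs
  and their summaries.
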