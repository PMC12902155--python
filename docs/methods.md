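# Methods

## Model

Background selection (BGS) is the reduction of neutral genetic diversity
caused by purifying selection against linked deleterious mutations. We
summarize it per genomic window as `B ∈ (0, 1]`, the ratio of expected
diversity with BGS to diversity without it; `B̄` is the callable-site
weighted genome-wide mean, and `Nmax` denotes the effective population size
absent BGS, so `B̄ = Ne / Nmax`.

### Per-site kernels

For a neutral site at recombination fraction `r` from a selected site with
per-site deleterious mutation rate `μ`, homozygous effect `s` and dominance
`h`, the exponent contribution under random mating is

    μ s h (1 + (−2r + s h (2r − 1))²) / (r + s h − r s h)²

which remains accurate up to unlinked sites (`r = 1/2`, where it reduces to
`8 μ s h/(1+s h)²`) and reduces to `μ(1+(sh)²)/(sh) ≈ μ/(sh)` at `r = 0`.
Under partial selfing at rate `α` the equilibrium inbreeding coefficient is
`F = α/(2−α)`; effective recombination shrinks to `r′ = r(1−F)`, dominance
moves toward one, `h′ = h(1−F) + F`, and the kernel becomes
`μ s h′ (1+2r)²/(r′ + s h′(1+2r))²`. `B = exp(−Σ terms)` over selected
sites. Only the product `s·h` is identifiable; `h = 0.5` is the default.

### Windowed decomposition

`B = Bb · Bw`. The between-window part `Bb` sums kernel contributions from
selected sites in *other* windows (per-window totals `μ·L_i`, midpoint map
distances through Haldane's function, `r = 1/2` across chromosomes),
integrated over a gamma DFE with mean `s̄` and shape `β`, truncated below at
`s = 3/(2 Ne h_eff)` where drift overwhelms selection. The within-window
part `Bw` averages the classic per-site exponent
`sh/(sh + r(1−sh))²` over uniformly placed selected and neutral positions
in a window of recombination fraction `R`:

    exponent = U (b − a ln(1 + b/a)) / b²,   a = s h_eff, b = R_eff (1 − s h_eff)

with `U = 2 μ L` the diploid deleterious rate of the window. The `R → 0`
limit is `U/(2 s h_eff) = μL/(s h_eff)`, the classic zero-recombination
exponent. This closed form was re-derived from the double integral (whose
naive transcription is degenerate in `R`) and is validated in the tests
against a brute-force position-grid oracle at `≤ 1e-4` relative error.

### Quadrature and interpolation

DFE integrals use Gauss–Legendre quadrature in log-`s` (96 nodes by
default) on the truncated support; a reference adaptive-quadrature path
(`bb_window`, relative tolerance 1e-6) backs the fast path in tests. For
genome-scale likelihoods the DFE-integrated exponent is tabulated on a grid
of 40 log-spaced `r` values (smallest inter-window `r` to 0.5) and 11
linear `R` values, interpolated linearly in the exponent and clamped (with
a warning) outside the grid. Interpolation error is held below 1e-3
absolute in `B`. Pairwise window sums use a precomputed log-binned
distance→selected-length matrix (2048 bins), making each B-map evaluation
a small matrix–vector product; binning error is covered by the same
interpolation tolerance checks.

### Coalescent-Ne transition and epoch B-maps

Immediately after sampling, lineages have not yet sorted into the
least-loaded fitness class, so the coalescent Ne declines from `Nmax`
toward `B·Nmax` over a time scale set by `s h`. We model the decline as
`Ne(t) = Nmax (1 − (1−B) G(t))` with
`G(t) = E_f [(1 − e^{−s h′ t})²]` over the truncated DFE. We renormalize
the truncated integral so that `Ne(∞) = B·Nmax` exactly (the literal
unnormalized form is available behind a flag). For likelihood work the
continuous curve is condensed into a two-step transition: breakpoints where
`G` reaches 1/2 and 19/20, each step taking the `Ne(t)` value at its
interval midpoint. The transition speed is shared genome-wide and
conditioned on the coalescent Ne implied by observed genome-wide diversity
(`π/(4 μ_n)`), which is held fixed during optimization.

Because the truncation bound depends on each epoch's coalescent Ne
(`B̄_t N_t/(1+F)`), which depends on the B-map, per-epoch B-maps are
iterated to a fixed point (relative tolerance 1e-3 on `B̄_t N_t`, maximum
50 iterations; strong-selection DFEs converge in 2–3).

## Likelihoods

**Classic-BGS** (windowed diversity): each window contributes
`p_i ln(θ_i/(θ_i+1)) + m_i ln(1/(θ_i+1))` with
`θ_i = B_i · 4 Nmax μ_n / (1+F)`; `p_i` is the mean over sample pairs of
pairwise-polymorphic site counts (`Σ_sites 2j(n−j)/(n(n−1))`, fractional
values allowed), `m_i` the monomorphic remainder. Free parameters:
`Nmax, μ, s̄, β`; the neutral rate `μ_n` and `h` are fixed beforehand.
Windows with fewer than 1,000 callable sites (configurable) are excluded
from the likelihood but kept in the B-map.

**BGS-with-demography** (windowed unfolded SFS): demography is
piecewise-constant (`N_t`, boundaries `T_t`, most recent first) and shared
genome-wide; each window's coalescent history rescales every epoch by that
window's epoch-specific `B` and prepends the two-step transition. Expected
spectra come from closed-form expected branch lengths of the
piecewise-constant coalescent: the lineage-count process is a pure death
chain whose occupancy probabilities are exponential mixtures in cumulative
coalescent time; mixture coefficients are accumulated in extended precision
(long double), which keeps sample sizes up to a few tens well-conditioned.
Constant-size spectra reproduce `E[l_j] = 4N/j` to 1e-10 relative, and
piecewise spectra are cross-checked against a Monte-Carlo genealogy
oracle and msprime. The composite likelihood is
`Σ_i Σ_j p_{ij} ln ξ_{ij}` with the monomorphic class as bin 0.

Under partial selfing all coalescence rates gain a factor `(1+F)`, and
diploid sampling is compounded with non-HWE genotype frequencies
(`P(het) = 2p(1−p)(1−F)`): each diploid's two lineages are identical by
descent with probability `F`, the IBD count mixes binomially, and a
hypergeometric map converts distinct-lineage spectra into sampled-allele
spectra. In the `F → 1` limit this reproduces the spectrum of `n/2`
haploids with doubled counts.

Polarization error `ε` mixes frequency classes `j` and `n−j`
(`ξ′_j = (1−ε)ξ_j + ε ξ_{n−j}`, fixed-derived class taken as zero) and is
estimated beforehand by fitting a neutral multi-epoch model with `ε` free
to the genome-wide SFS. The selfing rate is likewise fixed beforehand, from
`F_IS` (`α = 2F/(1+F)`) or a neutral SFS fit; a free-`α` mode exists but
converges slowly and warns.

**Masked bins.** High-frequency bins (`n−1`, `n−2`) can be masked for data
with suspected reference/polarization bias. Masked terms are dropped
without renormalizing `ξ`; note this makes the objective slightly improper
(mass can be shifted into masked bins "for free"), so masked fits are
conservative about old-epoch sizes. Recovery tests therefore fit unmasked
data; masking is a data-quality tool, not a default.

## Optimization

Two-step derivative-free maximization: a Controlled Random Search (CRS2
with local mutation; population `max(10(d+1), 50)` uniform in box bounds,
simplex-reflection trials replacing the worst member, stop at a 1e-3
objective spread or the evaluation cap), then a bounded Nelder–Mead polish
that never returns a worse point. `Nmax/N_t/T_t/μ/s̄/β` are optimized on
log10 scale. During the CRS phase per-window B values are rounded to two
decimals so that many windows share an expected SFS (grouped and cached);
the polish uses unrounded B. Everything is deterministic given a seed.
Confidence intervals come from percentile bootstrap (2.5/97.5) over
resampled replicate units, with failed refits counted and excluded.

## Synthetic data and oracles

The toy-genome generator emulates the features real analyses condition on:
heterogeneous selected-site density (slot-based blocks with a sinusoidal
keep probability; optionally gene-free chromosomes, which provide the
`B ≈ 1` windows that identify `Nmax`), uniform or hotspot recombination,
and fixed-width windows. Samplers draw windowed SFS (multinomial per
window) or pairwise diversity (binomial) from the model's own expected
values; a `depth` factor pools independent replicates of the same genome,
mirroring the pooling of forward-simulation replicates in simulation
studies. The samplers condition their truncation/transition Ne on the
model's own expected diversity, exactly as a subsequent fit conditions on
observed diversity.

Two independent oracles validate the analytics:

* a Monte-Carlo coalescent (vectorized over replicates) for expected
  branch-length spectra and pairwise coalescence times, with selfing
  handled as instant within-diploid coalescence with probability `F` plus
  `(1+F)`-rescaled rates;
* a forward Wright–Fisher population: multiplicative fitness, gamma
  deleterious effects confined to annotated blocks, neutral mutations
  tracked elsewhere, crossovers per the map (per-site phase sweep in a
  compiled kernel, exact for a no-interference crossover process), selfing
  with probability `α`, burn-in `12N/(1+F)` generations, diversity measured
  population-wide at neutral sites. `B̂ = π/(4Nμ_n/(1+F))`.

### Validation scales and what they show

The forward cross-validation runs at `N = 400` on a 2 Mb genome of 16
chromosomes with a dense map (0.075 M per chromosome), deleterious rate
1e-8 on 30% of sites and a strong-selection DFE (`s̄ = 0.02, β = 3`), with
~20 replicates; the replicate spread is dominated by genealogical noise
(roughly independent genealogies per chromosome arm), which sets the
0.03-absolute agreement band. At several-fold heavier deleterious load the
forward simulation sits visibly below the pairwise prediction — the
expected signature of multi-locus interference, which the theory's
independence assumption excludes; the validation regime keeps per-pair
interference weak (`2Nsh ≫ 1`, small per-chromosome exponent). Parameter
recovery runs use 2,000–4,000 windows of 10 kb with pooling depth 10
(growth and decline two-epoch truths at the standard five-fold-change
design) and recover demographic parameters within 10%, `Nmax` within 5%
and `μ` within 15%; `β` is weakly identified by construction and only
bracketed. Passing these tests shows internal consistency and agreement
with independent simulation at desk scale; it does not certify behavior on
real data with misspecified annotations, maps, or strong population
structure, none of which the generator emulates.

## Numerical choices and edge cases

* `s h = 0` with `r = 0` raises (the truncation bound should exclude it);
  a truncation bound ≥ 1 short-circuits to `B = 1`.
* `ξ` is floored at 1e-300 before logs; observed counts on numerically
  zero expectations raise a data/model mismatch error.
* Transition epochs longer than `T0` are compressed into the first epoch
  with a warning.
* The expected-SFS engine refuses `θ` per site large enough to make the
  monomorphic class negative (infinite-sites violation).
* Windows with zero callable sites stay in B-maps but never enter
  likelihoods; selected features spanning window boundaries are
  apportioned by overlap length.

## Known limitations

* No interference/multi-locus disequilibrium corrections: at very high
  selfing (`α ≈ 0.98`) or heavy deleterious load the pairwise theory
  underestimates the diversity reduction.
* No migration or population structure; no sweeps; no gene conversion; no
  sex-specific maps.
* The two-step transition and the shared genome-wide transition speed are
  deliberate simplifications; they are accurate where BGS is strong (low
  recombination) and matter little elsewhere.
* `β` (DFE shape) is close to unidentifiable from diversity landscapes
  alone; treat its point estimates as decorative.
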