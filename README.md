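# bgsinfer

Estimating the reduction in genetic diversity caused by background
selection (BGS) — the removal of linked neutral variation by purifying
selection against deleterious mutations — from genome sequence data, under
non-equilibrium demography and partial self-fertilization.

The package is aimed at population geneticists working with windowed
summaries of polymorphism data (nucleotide diversity or unfolded site
frequency spectra) together with a genome annotation of selected sites and
a recombination map. It provides three estimators:

* **classic-BGS**: composite likelihood of windowed pairwise diversity.
  Per window, `θ_i = B_i · 4 N_max μ_n`, where the B-map
  `B_i = B_b,i · B_w,i` follows from integrating the per-site exponent

      μ s h (1 + (−2r + s h (2r − 1))²) / (r + s h − r s h)²

  over a gamma distribution of fitness effects (mean `s̄`, shape `β`,
  truncated below `s = 3/(2 N_e h)`), across all selected sites at
  recombination fraction `r` (Haldane's function of map distance). Free
  parameters: `N_max, μ, s̄, β`; `B̄ = N_e/N_max` is the genome-wide
  reduction.
* **BGS-with-demography**: composite likelihood of windowed unfolded SFS
  under a piecewise-constant history whose epochs are rescaled per window
  by epoch-specific `B`, including the recent transition of coalescent
  `N_e` from `N_max` toward `B·N_max`, and a polarization-error operator
  `ξ′_j = (1−ε)ξ_j + ε ξ_{n−j}`. Jointly estimates demography
  (`N_0, N_1, T_0, …`) and the DFE, correcting demographic inference for
  BGS.
* **BGS-with-partial-selfing**: either of the above with the selfing
  rescalings `F = α/(2−α)`, `r′ = r(1−F)`, `h′ = h(1−F)+F`, coalescence
  rates × `(1+F)`, and inbreeding-aware diploid sampling
  (`P(het) = 2p(1−p)(1−F)`).

A synthetic-data module (toy genomes, model-exact samplers, a Monte-Carlo
coalescent and a forward Wright–Fisher simulator with selection and
selfing) makes every stage testable without external data, and doubles as
the package's independent ground truth.

## Worked example

```python
import numpy as np
from bgsinfer import (ClassicModelConfig, GammaDFE, ToyGenomeConfig,
                      fit_classic, make_toy_genome, sample_windowed_diversity)
from bgsinfer.bgs_theory import bmap_for_genome

# a 40 Mb toy genome (4 chromosomes, 20% coding, uniform map)
cfg = ToyGenomeConfig(n_chromosomes=4, chrom_length=10_000_000,
                      selected_fraction=0.2, rate=1e-8, seed=7)
rmap, ann, genome = make_toy_genome(cfg, mu=7.5e-9)

# simulate windowed diversity from a known B-map, then fit it back
dfe = GammaDFE(mu=7.5e-9, s_mean=0.01, beta=3.0)
B, _, _ = bmap_for_genome(genome, dfe, Ne=10_000.0)
data = sample_windowed_diversity(genome, B, Nmax=10_000.0, mu_n=7.5e-9, seed=42)

pi = data.p.sum() / (data.p + data.m).sum()
config = ClassicModelConfig(Nmax=1e4, mu_n=7.5e-9, dfe=dfe,
                            Ne_truncation=pi / (4 * 7.5e-9))
res = fit_classic(data, genome, config,
                  {"Nmax": (1e3, 1e5), "mu": (1e-10, 1e-7),
                   "s_mean": (1e-4, 0.2), "beta": (0.1, 10.0)},
                  seed=1, max_evals=2000)
print(round(res.params["Nmax"]), round(res.extras["Bbar"], 3),
      round(np.average(B, weights=genome.callable), 3))
```

prints

```
10154 0.766 0.779
```

i.e. the fitted effective size absent BGS (truth 10,000), the fitted
genome-wide `B̄`, and the generative `B̄`: background selection removed
~22% of neutral diversity on this genome, and the fit recovers the scale
within 2% and the reduction within 0.013. The `examples/` directory has one short script
per capability (B-map prediction, classic fit, joint SFS fit, partial
selfing, forward-simulation cross-validation).

A thin CLI mirrors the main workflows for shell use:
`bgsinfer tally`, `bgsinfer fit-classic`, `bgsinfer fit-joint`
(see `bgsinfer --help`; bounds files are TOML tables of `[low, high]`).

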