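"""Background selection under partial self-fertilization.

Shows the three selfing rescalings: F = alpha/(2-alpha), effective
recombination r' = r(1-F) and dominance h' = h(1-F)+F, and the (1+F)
coalescent rate scaling; then fits the pi-only BGS-with-partial-selfing
model to data simulated at alpha = 0.9 and reports the recovered B-bar.
"""

import numpy as np

from bgsinfer import (ClassicModelConfig, GammaDFE, MatingSystem,
                      ToyGenomeConfig, make_toy_genome,
                      sample_windowed_diversity)
from bgsinfer.bgs_theory import bmap_for_genome
from bgsinfer.sfs_likelihood import fit_pi_selfing

alpha = 0.9
mating = MatingSystem(alpha)
print(f"alpha = {alpha}:  F = {mating.F:.4f}, "
      f"r' = r * {1 - mating.F:.4f}, h'(0.5) = {mating.h_eff(0.5):.4f}, "
      f"coalescence rate x {1 + mating.F:.4f}")

cfg = ToyGenomeConfig(n_chromosomes=5, chrom_length=2_000_000,
                      selected_fraction=0.25, rate=1.5e-8,
                      density_amplitude=0.9, gene_free_chromosomes=1, seed=7)
rmap, ann, genome = make_toy_genome(cfg, mu=7.5e-9)

dfe = GammaDFE(7.5e-9, 0.01, 0.333)  # includes weakly deleterious mutations
Nmax = 10_000.0

# self-consistent truth B-map: the DFE truncation depends on coalescent Ne,
# which depends on B-bar
Ne = Nmax / (1 + mating.F)
for _ in range(20):
    B, _, _ = bmap_for_genome(genome, dfe, Ne, mating)
    Ne_new = np.average(B, weights=genome.callable) * Nmax / (1 + mating.F)
    if abs(Ne_new / Ne - 1) < 1e-4:
        break
    Ne = Ne_new
b_truth = float(np.average(B, weights=genome.callable))

data = sample_windowed_diversity(genome, B, Nmax, 7.5e-9, seed=21, F=mating.F)
pi = data.p.sum() / (data.p + data.m).sum()
config = ClassicModelConfig(Nmax=Nmax, mu_n=7.5e-9, dfe=dfe, mating=mating,
                            Ne_truncation=pi / (4 * 7.5e-9))
bounds = {"Nmax": (1e3, 1e5), "mu": (1e-10, 1e-7),
          "s_mean": (1e-5, 0.2), "beta": (0.05, 10.0)}
res = fit_pi_selfing(data, genome, config, bounds, seed=11, max_evals=1500)

print(f"\ntruth B-bar under selfing: {b_truth:.4f}")
print(f"fitted B-bar:              {res.extras['Bbar']:.4f}")
print(f"fitted Nmax:               {res.params['Nmax']:.0f} (truth {Nmax:.0f})")
print("\nHigh selfing deepens BGS (low effective recombination) while also")
print("halving diversity via the (1+F) coalescent rescaling; the fit")
print("separates the two effects given alpha.")
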