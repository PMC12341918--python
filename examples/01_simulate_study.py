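"""Simulate a small 2x-4x triploid breeding study and describe its layout.

The generator draws a diploid SNP panel, doubles part of it into tetraploid
parents, crosses them into triploid families of unequal size, and lays the
hybrids out in blocks of 56 plus 8 control plants (five replicates of a
Cavendish-type check), phenotyped over three crop cycles with correlated
errors.
"""

from triploidcross import SimulationConfig, simulate_dataset

config = SimulationConfig(n_parents2x=10, n_parents4x=10, n_crosses=25,
                          family_sizes=None, seed=7)
data = simulate_dataset(config)

ped = data.tables.pedigree
phe = data.tables.phenotypes
sizes = ped.groupby("family_id").size()
print(f"parents: {config.n_parents2x} diploid + {config.n_parents4x} "
      "doubled-diploid tetraploid")
print(f"crosses: {ped.groupby(['parent2x_id', 'parent4x_id']).ngroups}, "
      f"hybrids: {len(ped)}, family sizes {sizes.min()}-{sizes.max()}")
print(f"blocks: {phe['block_id'].nunique()} (56 hybrids + 8 controls each), "
      f"phenotype records: {len(phe)}")
print("realized variance components (empirical variances of the drawn "
      "effects):")
for k, v in data.truth.realized_components.items():
    print(f"  {k:10s} = {v:.3f}")
print("Each hybrid's true clonal value decomposes exactly into "
      "2x GCA + 4x GCA + SCA + within-cross deviation.")
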