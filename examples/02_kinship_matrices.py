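"""Build the genomic covariance structures of the 2x-4x model.

AD and AT are the ploidy-general additive GRMs of the diploid and
tetraploid parents; F is the expected inbreeding of each cross's triploid
progeny under polysomic 4x meiosis; D is the expected dominance
relationship between crosses; the epistasis matrix is a principal
submatrix of the Kronecker product AD x AT.
"""

import numpy as np

from triploidcross import (SimulationConfig, additive_grm, build_kinship_set,
                           simulate_dataset)

data = simulate_dataset(SimulationConfig(n_parents2x=8, n_parents4x=8,
                                         n_crosses=20, family_sizes=5,
                                         seed=11))
ped = data.tables.pedigree
crosses = sorted(set(zip(ped["parent2x_id"], ped["parent4x_id"])))
kin = build_kinship_set(data.genotypes, crosses)

# doubling identity: a tetraploid that is a doubled diploid has exactly
# twice the diploid relationship under the ploidy-general GRM
dos = data.genotypes.dosages[:4].astype(float)
A2 = additive_grm(dos, 2, data.genotypes.freqs)
A4 = additive_grm(2 * dos, 4, data.genotypes.freqs)
print(f"AT / AD entrywise ratio (doubled diploids): "
      f"{np.mean(A4[np.abs(A2) > 1e-9] / A2[np.abs(A2) > 1e-9]):.3f}")

print(f"AD: {kin.AD.shape[0]} diploid parents, mean diagonal "
      f"{np.diag(kin.AD).mean():.3f}")
print(f"AT: {kin.AT.shape[0]} tetraploid parents, mean diagonal "
      f"{np.diag(kin.AT).mean():.3f}")
print(f"expected cross inbreeding F: {kin.F.min():.3f} .. {kin.F.max():.3f} "
      "(positive: bivalent pairing of doubled chromosomes creates "
      "autozygosity)")
print(f"dominance GRM diagonal: {np.diag(kin.Dmat).mean():.3f} (mean)")
print(f"epistasis matrix smallest eigenvalue: "
      f"{np.linalg.eigvalsh(kin.Kepi).min():.2e} (PSD)")
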