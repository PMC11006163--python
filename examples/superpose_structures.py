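"""Kabsch superposition of CA traces: rigid-motion recovery and noisy RMSD.

Builds a synthetic four-helix bundle, moves a copy by a random rigid motion
(which superposition must undo exactly) and then adds coordinate noise
(which sets a floor on the achievable RMSD).
"""

import numpy as np

import qtycode as q

bundle = q.generate_helix_bundle(seed=1, n_helices=4, residues_per_helix=20)
rng = np.random.default_rng(0)

moved = bundle.transformed(q.random_rotation(rng), rng.normal(size=3) * 10)
exact = q.kabsch_superpose(moved, bundle)
print(f"rigid copy     rmsd = {exact.rmsd:.2e} A over {exact.n_pairs} CA pairs")

noisy = q.perturb_structure(moved, sigma=0.5, seed=7)
fitted = q.kabsch_superpose(noisy, bundle)
print(f"noisy copy     rmsd = {fitted.rmsd:.3f} A  (0.5 A isotropic noise per atom)")

# A pure rigid motion superposes back to numerical zero; with 0.5 A noise on
# each coordinate the best achievable RMSD is about sigma * sqrt(3) ~ 0.87 A,
# the scale to keep in mind when reading sub-Angstrom RMSDs between a native
# structure and a redesigned variant.
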