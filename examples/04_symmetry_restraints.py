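"""Cyclic symmetry as distance-equality restraints, no symmetry axis needed.

Builds C7 restraints for a seven-membered ring, confirms the exact ring has
zero violation energy, then perturbs one subunit and lets orientation-only
minimization restore the symmetry.
"""
import numpy as np

from emassemble.minimize import EnergyStack, orientation_only_minimize
from emassemble.protocol import symmetry_term
from emassemble.restraints import build_cx_restraints, symmetry_energy
from emassemble.synthetic import (RingSpec, ToySpec, make_toy_assembly,
                                  perturb_assembly)

spec = ToySpec(rings=(RingSpec(count=7, radius=28.0, z=0.0),))
assembly, subunit = make_toy_assembly(spec)
restraints = build_cx_restraints(list(subunit.backbone_indices), 7)
print(f"C7 restraints: {restraints.n_sets} equality sets of "
      f"{restraints.set_size} distances each (3 sets per bead pair)")

e0, _ = symmetry_energy(assembly, restraints)
print(f"exact ring energy: {e0:.2e}")

rng = np.random.default_rng(0)
broken = perturb_assembly(assembly, 0.0, 0.5, rng)
e1, _ = symmetry_energy(broken, restraints)
res = orientation_only_minimize(broken, EnergyStack(terms=[symmetry_term(restraints)]),
                                max_iter=100)
print(f"after random spins: {e1:.3g}; after orientation-only minimization: "
      f"{res.energy:.3g}")
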