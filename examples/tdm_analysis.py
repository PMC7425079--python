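"""From a transition density matrix to fragment descriptors.

A one-electron transition density matrix D (row = hole AO, column =
electron AO) and the AO overlap S are reduced to fragment charge-transfer
numbers Ω_AB; everything else — electron/hole populations, CT character,
NTO weights, SIEL — follows from Ω.  A seeded toy TDM whose electron weight
is piled on bpy1 stands in for a quantum-chemistry matrix.
"""

import numpy as np

from sielkit import (
    FragmentScheme,
    ct_character,
    electron_populations,
    generate_toy_tdm,
    hole_populations,
    nto_weights,
    omega_matrix,
    siel_state,
)

scheme = FragmentScheme(
    ["Ru", "bpy1", "bpy2", "bpy3"],
    ["metal", "ligand", "ligand", "ligand"],
    substituted_index=1,
)

ctx = generate_toy_tdm(n_ao=12, scheme=scheme, target_electron_fragment=1, seed=7)
om = omega_matrix(ctx, scheme, style="mulliken")

np.set_printoptions(precision=3, suppress=True)
print("Omega (rows = hole fragment, cols = electron fragment):")
print(om.omega / om.omega_total)
print("electron populations:", electron_populations(om))
print("hole populations:    ", hole_populations(om))
print("CT character:", {k: round(v, 3) for k, v in ct_character(om).items()})
print("NTO weights:", np.round(nto_weights(ctx), 3))
print(f"SIEL(bpy1) = {siel_state(electron_populations(om), scheme):+.3f}")

# The electron populations peak on bpy1 by construction, so SIEL is
# negative (attraction).  The NTO weights say how many hole–electron
# orbital pairs the excitation needs: a single weight near 1 means a clean
# one-pair transition.
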