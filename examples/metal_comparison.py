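"""Metal substitution: coordination geometry and reaction energetics.

Swaps the cation's radius/charge parameters (geometry untouched), relaxes
the active-site cluster in the no-repacking control mode, and compares
coordination distances and the ZPE-corrected energetics of the transfer
step across the four stock metal parameterizations.
"""

import numpy as np

from qmdmd import mechanism, synthetic
from qmdmd.backend import SurrogateBackend
from qmdmd.driver import static_cluster_mode

system, _truth = synthetic.make_toy_site()
m = system.metal_id
donors = system.backend_params.morse_j
donor_names = [system.atoms[j].atom_name for j in donors]

print("metal   radius  charge   mean M–donor (Å)   ΔE‡      ΔE_rxn (kcal/mol)")
rows = {}
for preset in ("mg", "ca", "fe2", "fe3"):
    label, radius, charge = synthetic.METAL_PRESETS[preset]
    variant = synthetic.make_metal_variant(system, radius, charge,
                                           label=label)
    cluster, _res = static_cluster_mode(variant)
    full, _mask = cluster.full_positions(variant.positions)
    mean_d = float(np.mean(np.linalg.norm(full[donors] - full[m], axis=1)))
    backend = SurrogateBackend(variant.backend_params)
    r, ts, p = mechanism.transfer_path(cluster, backend, system.masses,
                                       n_scan=31)
    de_ts = ts.corrected_energy - r.corrected_energy
    de_rxn = p.corrected_energy - r.corrected_energy
    rows[preset] = (mean_d, de_ts, de_rxn)
    print(f"{preset:6s} {radius:6.3f} {charge:+6.1f} {mean_d:14.3f} "
          f"{de_ts:10.2f} {de_rxn:10.2f}")

print("\nlarger cation (ca vs mg): every coordination distance lengthens and "
      "the reaction end-point rises — the inhibition-by-size analog")
print("higher charge (fe3 vs fe2): both the barrier and the reaction energy "
      "rise — the electrophilic-cation analog (reactant stabilization)")
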