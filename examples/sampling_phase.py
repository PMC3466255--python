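"""One event-driven sampling phase with hard constraint windows.

Runs a single constant-temperature production phase of the discrete
molecular dynamics sampler: the metal core is frozen, covalent bonds and
QM-derived constraint windows are infinite square wells, and an
Andersen-style thermostat holds the reduced temperature.  Printed numbers
show the three guarantees the sampler makes: snapshot accounting, exact
constraint enforcement, and the thermostat set-point.
"""

import numpy as np

from qmdmd import synthetic
from qmdmd.dmd import DMDParams, build_potentials, run_phase
from qmdmd.driver import default_constraint_pairs
from qmdmd.partition import (assign_domains, constraints_from_cluster,
                             extract_capped_cluster)

system, _truth = synthetic.make_toy_site()
partition = assign_domains(system)
cluster = extract_capped_cluster(system, partition)
constraints = constraints_from_cluster(cluster,
                                       default_constraint_pairs(system))
table = build_potentials(system, constraints, partition)

params = DMDParams(temperature=0.10, heat_exchange_rate=0.1,
                   duration=2000.0, save_interval=10.0, seed=7)
traj = run_phase(system, partition, table, params)

theta = traj.kinetic_energies.mean() / (1.5 * traj.n_free)
print(f"phase: {params.duration:g} t.u., saved every {params.save_interval:g} "
      f"t.u. -> {traj.n_snapshots} snapshots ({traj.n_events} events)")
print(f"free atoms: {traj.n_free}; recovered reduced temperature "
      f"2<KE>/3N = {theta:.4f} (set-point {params.temperature})")
print(f"{len(constraints)} constraint windows of ±0.01 Å; largest deviation "
      f"seen at any event or snapshot: {traj.max_constraint_dev:.6f} Å")
dev = np.abs(np.diff(traj.times) - params.save_interval).max()
print(f"snapshot spacing uniform to {dev:.1e} t.u. — the sampler walks the "
      "flat stepwise wells without ever leaving a hard window")
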