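"""Compare all stationary solvers on the dual PdPC at N=205 (monostable and bistable).

Prints the lattice maximum rho_max of each method and its error against the
exact stationary solution: the l1 distance and the base-2 Jensen-Shannon
distance (as a percentage).  The RWA is global (one formula for the whole
lattice); SSE and the frozen-rate multinomial are local expansions around the
stable critical point(s).
"""

import rwagraph as rw

N = 205
lattice = rw.enumerate_lattice(N, 3)
for v2 in (1.82, 3.04):
    regime = "monostable" if v2 < rw.pdpc_bistability_threshold() else "bistable"
    model = rw.pdpc_model(rw.PdpcParams(v2=v2))
    exact = rw.compute_distribution("exact", model, N, lattice=lattice)
    print(f"\ndual PdPC, v2={v2} ({regime}), N={N}:")
    print(f"  exact        rho_max={exact.max_prob():.3e}")
    for method in ("rwa", "sse", "multinomial"):
        dist = rw.compute_distribution(method, model, N, lattice=lattice)
        print(
            f"  {method:<12} rho_max={dist.max_prob():.3e}  "
            f"l1={rw.l1_distance(dist, exact):.3f}  "
            f"JS={100 * rw.js_distance(dist, exact):.1f}%"
        )

print(
    "\nrho_max quantifies peak sharpness (the multinomial is far too peaked); "
    "the JS percentage measures the information mismatch over the whole lattice."
)
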