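"""Run a small error sweep and export a heatmap grid, via the workbench layer.

Produces the long-format TSV schema used by all sweep experiments and a
dense (n_A, n_C) rho/rho_max grid of the bistable RWA, both under scratch/.
"""

from pathlib import Path

import rwagraph as rw
from rwagraph.workbench import SweepSpec, run_sweep

out_dir = Path("scratch")
out_dir.mkdir(exist_ok=True)

spec = SweepSpec(
    model="toy",
    sweep_param="alpha",
    sweep_values=[0.2, 0.4],
    N_values=[30, 60],
    methods=["rwa", "multinomial"],
    reference="exact",
    metrics=["l1", "js"],
    seed=0,
)
table = run_sweep(spec, out_path=out_dir / "toy_sweep.tsv")
print(table.to_string(index=False))

result = rw.rwa_distribution(rw.pdpc_model(rw.PdpcParams(v2=3.04)), 80)
grid = rw.export_heatmap(result.dist, out_dir / "pdpc_rwa_heatmap.txt")
print(f"\nheatmap grid {grid.shape}, rho_max={result.dist.max_prob():.3e}")
print("Each sweep row is one (alpha, N, method, metric) cell; rerunning resumes, not recomputes.")
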