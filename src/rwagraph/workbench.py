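"""Experiment orchestration: configs, method dispatch, sweeps, heatmap export.

The workbench ties the solvers together behind a uniform "method" interface
(rwa, exact, gillespie, sse, multinomial), reads plain-text key=value model
configs, runs deterministic resumable parameter/N sweeps producing a single
long-format TSV schema, and exports dense (nA, nC) probability grids for
heatmaps.
"""

from __future__ import annotations

import configparser
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import StateGraphModel
from .exact import build_generator, gillespie_sample, stationary_nullspace
from .lattice import LatticeDistribution, SimplexLattice, enumerate_lattice
from .metrics import covariance_error, js_divergence, l1_distance
from .models import make_model
from .rwa import rwa_distribution
from .sse import multinomial_approximation, sse_distribution

__all__ = [
    "SweepSpec",
    "METHODS",
    "compute_distribution",
    "run_sweep",
    "export_heatmap",
    "load_model_config",
    "provenance_header",
]

log = logging.getLogger("rwagraph")

METHODS = ("rwa", "exact", "gillespie", "sse", "multinomial")
_METRICS = {"l1": l1_distance, "js": js_divergence, "cov_error": covariance_error}


@dataclass
class SweepSpec:
    """Declarative description of an error-vs-parameter/N sweep."""

    model: str
    fixed_params: dict = field(default_factory=dict)
    sweep_param: str | None = None
    sweep_values: Sequence[float] = ()
    N_values: Sequence[int] = ()
    methods: Sequence[str] = ("rwa",)
    reference: str = "exact"
    metrics: Sequence[str] = ("l1", "js", "cov_error")
    seed: int = 0
    gillespie_events: int = 1_000_000
    gillespie_burn_in: int = 10_000

    def __post_init__(self):
        if not self.N_values:
            raise ValueError("N grid must be non-empty")
        if not self.methods:
            raise ValueError("methods list must be non-empty")
        bad = (set(self.methods) | {self.reference}) - set(METHODS)
        if bad:
            raise ValueError(f"unknown methods {sorted(bad)}; known: {METHODS}")
        if self.sweep_param is not None and not list(self.sweep_values):
            raise ValueError("sweep grid must be non-empty")


def compute_distribution(
    method: str,
    model: StateGraphModel,
    N: int,
    lattice: SimplexLattice | None = None,
    seed: int = 0,
    gillespie_events: int = 1_000_000,
    gillespie_burn_in: int = 10_000,
) -> LatticeDistribution:
    """Run one named method and return its lattice distribution."""
    if lattice is None:
        lattice = enumerate_lattice(N, model.M)
    if method == "rwa":
        return rwa_distribution(model, N, lattice=lattice).dist
    if method == "exact":
        return stationary_nullspace(build_generator(model, N, lattice=lattice))
    if method == "sse":
        return sse_distribution(model, N, lattice=lattice, seed=seed)
    if method == "multinomial":
        return multinomial_approximation(model, N, lattice=lattice, seed=seed)
    if method == "gillespie":
        return gillespie_sample(
            model,
            N,
            n_events=gillespie_events,
            burn_in=gillespie_burn_in,
            seed=seed,
            lattice=lattice,
        )
    raise ValueError(f"unknown method {method!r}")


def run_sweep(spec: SweepSpec, out_path=None) -> pd.DataFrame:
    """Run a sweep and return one row per (param value, N, method, metric).

    Deterministic given ``spec.seed``.  When ``out_path`` exists, rows already
    present there are skipped and the merged table is rewritten (resumable
    sweeps); per-cell solver failures are logged and marked with NaN values,
    and the sweep continues.
    """
    done = set()
    old = None
    if out_path is not None:
        try:
            old = pd.read_csv(out_path, sep="\t", comment="#")
            done = {
                (r.param_value, r.N, r.method, r.metric) for r in old.itertuples(index=False)
            }
        except (FileNotFoundError, pd.errors.EmptyDataError):
            old = None

    param_values = list(spec.sweep_values) if spec.sweep_param else [float("nan")]
    rows = []
    for pv in param_values:
        params = dict(spec.fixed_params)
        if spec.sweep_param:
            params[spec.sweep_param] = pv
        model = make_model(spec.model, **params)
        for N in spec.N_values:
            lattice = enumerate_lattice(int(N), model.M)
            cell = [
                m
                for m in spec.methods
                if any((pv, N, m, met) not in done for met in spec.metrics)
            ]
            if not cell:
                continue
            log.info("sweep cell: %s=%s N=%s", spec.sweep_param, pv, N)
            try:
                ref = compute_distribution(
                    spec.reference,
                    model,
                    int(N),
                    lattice=lattice,
                    seed=spec.seed,
                    gillespie_events=spec.gillespie_events,
                    gillespie_burn_in=spec.gillespie_burn_in,
                )
            except Exception as err:  # noqa: BLE001 - sweep must continue
                log.error("reference %s failed at %s=%s N=%s: %s", spec.reference, spec.sweep_param, pv, N, err)
                for m in cell:
                    for met in spec.metrics:
                        rows.append((pv, int(N), m, met, float("nan")))
                continue
            for m in cell:
                try:
                    dist = compute_distribution(
                        m,
                        model,
                        int(N),
                        lattice=lattice,
                        seed=spec.seed,
                        gillespie_events=spec.gillespie_events,
                        gillespie_burn_in=spec.gillespie_burn_in,
                    )
                    for met in spec.metrics:
                        if (pv, N, m, met) in done:
                            continue
                        rows.append((pv, int(N), m, met, float(_METRICS[met](dist, ref))))
                except Exception as err:  # noqa: BLE001
                    log.error("method %s failed at %s=%s N=%s: %s", m, spec.sweep_param, pv, N, err)
                    for met in spec.metrics:
                        rows.append((pv, int(N), m, met, float("nan")))

    table = pd.DataFrame(rows, columns=["param_value", "N", "method", "metric", "value"])
    table.insert(0, "param", spec.sweep_param or "")
    table.insert(0, "model", spec.model)
    if old is not None and len(old):
        table = pd.concat([old, table], ignore_index=True) if len(table) else old
    if out_path is not None:
        with open(out_path, "w") as fh:
            fh.write(provenance_header(model=spec.model, params=spec.fixed_params, seed=spec.seed))
            table.to_csv(fh, sep="\t", index=False)
    return table


def export_heatmap(dist: LatticeDistribution, path) -> np.ndarray:
    """Write a dense (N+1) x (N+1) grid of rho/rho_max over (n_A, n_C).

    Rows index n_A, columns n_C; entries outside the simplex are 0.  The
    header records rho_max so the grid can be rescaled back to probabilities.
    Only defined for three-state lattices.
    """
    if dist.lattice.M != 3:
        raise ValueError("heatmap export is only defined for M=3 lattices")
    N = dist.lattice.N
    rho_max = dist.max_prob()
    grid = np.zeros((N + 1, N + 1))
    nA = dist.lattice.states[:, 0]
    nC = dist.lattice.states[:, 2]
    grid[nA, nC] = dist.prob / rho_max
    header = f"rho_max = {rho_max:.17g}\nrows n_A = 0..{N}, cols n_C = 0..{N}, values rho/rho_max"
    np.savetxt(path, grid, header=header)
    return grid


def load_model_config(path, section: str = "model") -> tuple[str, dict]:
    """Read a plain-text key=value config; returns (model name, parameter dict).

    The section must contain ``name``; every other key is parsed as a float
    parameter for the model family.
    """
    cp = configparser.ConfigParser()
    read = cp.read(path)
    if not read:
        raise FileNotFoundError(path)
    if section not in cp:
        raise ValueError(f"config {path} has no [{section}] section")
    items = dict(cp[section])
    try:
        name = items.pop("name")
    except KeyError:
        raise ValueError(f"config section [{section}] must set 'name'") from None
    return name, {k: float(v) for k, v in items.items()}


def provenance_header(**fields) -> str:
    """'# key = value' header lines recording what produced an output file."""
    fields = {"package": f"rwagraph {__version__}", **fields}
    return "".join(f"# {k} = {v}\n" for k, v in fields.items())
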