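"""Reproducible drivers: threshold curves, lattice parameter sweeps, and
invasion-probability estimation.

Every stochastic cell of a sweep derives its seed deterministically from
``(base_seed, cell index, replicate index)`` via a ``SeedSequence``, so
individual cells can be re-run (or parallelized) independently and results
with identical inputs are bit-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .analytic import threshold_table  # re-exported driver for threshold curves
from .core import ModelParams
from .spatial import SimConfig, run_simulation

__all__ = [
    "SweepSpec",
    "threshold_table",
    "lattice_sweep",
    "invasion_table",
    "validate_recursion",
    "cell_seed",
]

OUTCOMES = ("extinct", "fixed", "reached_target", "stabilized", "max_generations")


def cell_seed(base_seed: int, cell_index: int, replicate: int) -> int:
    """Deterministic per-replicate seed (below 2^31) for a sweep cell."""
    ss = np.random.SeedSequence([int(base_seed), int(cell_index), int(replicate)])
    return int(ss.generate_state(1)[0]) % 2**31


@dataclass
class SweepSpec:
    """A lattice sweep over equal horizontal-transmission probability T and b/c.

    ``T_values`` are the shared transmission probabilities (T_alpha =
    T_beta = T); ``bc_values`` the benefit/cost ratios at fixed cost ``c``
    (0.05 by default, matching the convention used throughout the
    simulation experiments). ``mode='genetic'`` runs the host-allele
    control, for which T is irrelevant and recorded as NaN.
    """

    T_values: tuple = (0.001, 0.01, 0.1, 0.5)
    bc_values: tuple = (3.0, 20.0, 100.0)
    c: float = 0.05
    K: int = 1
    VT: float = 1.0
    mode: str = "microbe"
    dims: tuple[int, int] = (100, 100)
    init_fraction: float = 0.05
    replicates: int = 30
    base_seed: int = 0
    max_generation: int = 10_000

    def cells(self) -> list[tuple[float, float]]:
        if self.mode == "genetic":
            return [(float("nan"), bc) for bc in self.bc_values]
        return [(T, bc) for T in self.T_values for bc in self.bc_values]


def _sweep_config(spec: SweepSpec, T: float, bc: float, seed: int) -> SimConfig:
    t = 0.0 if spec.mode == "genetic" else T
    params = ModelParams(
        b=bc * spec.c, c=spec.c, T_alpha=t, T_beta=t, VT=spec.VT
    )
    return SimConfig(
        params=params,
        K=spec.K,
        mode=spec.mode,
        dims=spec.dims,
        init=("random", spec.init_fraction),
        seed=seed,
        max_generation=spec.max_generation,
    )


def lattice_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Run the sweep; one row per cell.

    Columns: T, bc, mode, replicates, mean_final_p, plus one count column
    per outcome label. ``mean_final_p`` is the average over replicates of
    the proportion of altruists when the run stopped.
    """
    rows = []
    for ci, (T, bc) in enumerate(spec.cells()):
        finals = []
        tally = {k: 0 for k in OUTCOMES}
        for rep in range(spec.replicates):
            cfg = _sweep_config(spec, T, bc, cell_seed(spec.base_seed, ci, rep))
            res = run_simulation(cfg)
            finals.append(res.final_p)
            tally[res.outcome] += 1
        rows.append(
            {
                "T": T,
                "bc": bc,
                "mode": spec.mode,
                "replicates": spec.replicates,
                "mean_final_p": float(np.mean(finals)),
                **tally,
            }
        )
    return pd.DataFrame(rows)


def invasion_table(
    T_values,
    bc_values,
    c: float = 0.05,
    K: int = 1,
    VT: float = 1.0,
    mode: str = "microbe",
    dims: tuple[int, int] = (100, 100),
    patch_side: int = 2,
    replicates: int = 1000,
    base_seed: int = 0,
    target: float = 0.05,
) -> pd.DataFrame:
    """Estimate the probability that a tiny central patch of altruists grows.

    Each replicate starts from a central ``patch_side`` x ``patch_side``
    block of alpha-carriers and runs until the proportion of alpha reaches
    0, the ``target`` (0.05 by default), or stabilizes in between. The
    estimated probability of reaching the target carries a Wilson score
    interval (appropriate in the small-probability regime). Runs that
    stabilize below the target are counted as failures and tallied in the
    ``stabilized`` column.
    """
    rows = []
    cells = [(T, bc) for T in T_values for bc in bc_values]
    for ci, (T, bc) in enumerate(cells):
        t = 0.0 if mode == "genetic" else float(T)
        params = ModelParams(b=bc * c, c=c, T_alpha=t, T_beta=t, VT=VT)
        successes = 0
        tally = {k: 0 for k in OUTCOMES}
        for rep in range(replicates):
            cfg = SimConfig(
                params=params,
                K=K,
                mode=mode,
                dims=dims,
                init=("patch", patch_side),
                seed=cell_seed(base_seed, ci, rep),
                upper_target=target,
            )
            res = run_simulation(cfg)
            tally[res.outcome] += 1
            if res.outcome == "reached_target" or res.final_p >= target:
                successes += 1
        lo, hi = proportion_confint(successes, replicates, alpha=0.05, method="wilson")
        rows.append(
            {
                "T": T,
                "bc": bc,
                "mode": mode,
                "replicates": replicates,
                "successes": successes,
                "probability": successes / replicates,
                "ci_low": float(lo),
                "ci_high": float(hi),
                **tally,
            }
        )
    return pd.DataFrame(rows)


def validate_recursion(
    grid=None,
    N: int = 100_000,
    replicates: int = 200,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Cross-check the deterministic recursion against the finite-N simulator.

    For each parameter point, compares the analytic one-generation change
    in p with the Monte-Carlo mean over ``replicates`` populations of size
    ``N``; the ``z`` column is the discrepancy in standard-error units.
    """
    from .analytic import next_generation_proportion
    from .mixed import estimate_delta_p

    if grid is None:
        grid = default_validation_grid()
    rows = []
    for i, (p0, params) in enumerate(grid):
        analytic_dp = next_generation_proportion(p0, params) - p0
        sim_dp, se = estimate_delta_p(N, p0, params, replicates, cell_seed(base_seed, i, 0))
        rows.append(
            {
                "p0": p0,
                "b": params.b,
                "c": params.c,
                "T_alpha": params.T_alpha,
                "T_beta": params.T_beta,
                "VT": params.VT,
                "N": N,
                "replicates": replicates,
                "analytic_dp": analytic_dp,
                "sim_dp": sim_dp,
                "se": se,
                "z": (sim_dp - analytic_dp) / se if se > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def default_validation_grid() -> list[tuple[float, ModelParams]]:
    """20 parameter points spanning spread, decline, and threshold regimes."""
    pts: list[tuple[float, ModelParams]] = []
    for p0 in (0.1, 0.5):
        for T in (0.01, 0.1):
            for bc in (0.5 / T, 2.0 * (1 - T) / T):  # below / above threshold
                for VT in (1.0, 0.75):
                    pts.append(
                        (p0, ModelParams(b=bc * 0.05, c=0.05, T_alpha=T, T_beta=T, VT=VT))
                    )
    # unequal transmission probabilities and the exact equal-T threshold
    pts.append((0.3, ModelParams(b=1.0, c=0.05, T_alpha=0.2, T_beta=0.05, VT=1.0)))
    pts.append((0.3, ModelParams(b=1.0, c=0.05, T_alpha=0.05, T_beta=0.2, VT=0.5)))
    pts.append((0.5, ModelParams(b=0.45, c=0.05, T_alpha=0.1, T_beta=0.1, VT=1.0)))
    pts.append((0.2, ModelParams(b=0.5, c=0.05, T_alpha=0.0, T_beta=0.0, VT=1.0)))
    return pts
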