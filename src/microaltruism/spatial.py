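"""Spatial prisoner's-dilemma simulator on a non-toroidal lattice.

Hosts occupy every site of a 2D grid (default 100 x 100). Each generation
consists of ``K`` interaction sweeps — in each sweep every host, in a fresh
random order, initiates one interaction with a uniformly chosen Moore
neighbor — followed by reproduction in the style of Nowak & May: every site
of the next generation is colonized by a copy of the fittest host among the
site and its (up to eight) neighbors, ties broken uniformly at random.
Fitness is the accumulated payoff normalized by the number of interactions
the host actually took part in. In microbe mode an interaction between
hosts carrying different microbes may also transmit microbes horizontally
(payoff first, transmission second, and a transmitted microbe changes the
recipient's behaviour in its later interactions of the same generation);
with imperfect vertical transmission the offspring obtains, with
probability 1 - VT, the microbe of a random individual from its
neighborhood in the parent generation. The genetic control mode evolves
host alleles instead: vertical transmission is perfect and nothing is
transmitted horizontally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import generation_kernel, seed_kernel
from .core import ModelParams

__all__ = [
    "Lattice",
    "SimConfig",
    "RunResult",
    "init_random",
    "init_patch",
    "neighborhood",
    "run_generation",
    "run_simulation",
    "is_stable",
]

_SEED_MOD = 2**31  # numba's legacy seeding takes uint32; stay below 2^31


@dataclass
class Lattice:
    """Grid of agent states with per-site fitness bookkeeping.

    ``states`` holds 1 for alpha (or the altruism allele A) and 0 for beta
    (or the neutral allele E). ``payoff_sum`` and ``interaction_count``
    refer to the most recently simulated generation and are reset by each
    call to :func:`run_generation`.
    """

    states: np.ndarray  # int8, shape (rows, cols)
    mode: str = "microbe"  # "microbe" | "genetic"
    payoff_sum: np.ndarray | None = None
    interaction_count: np.ndarray | None = None

    @property
    def dims(self) -> tuple[int, int]:
        return self.states.shape

    @property
    def p(self) -> float:
        """Proportion of alpha-carriers (altruists)."""
        return float(self.states.mean())


@dataclass
class SimConfig:
    """Settings of a spatial run.

    ``init`` is either ``("random", fraction)`` — an exact count
    ``round(fraction * n_sites)`` of alpha sites placed uniformly without
    replacement — or ``("patch", side)`` — a central side x side alpha
    block. ``upper_target`` is 1.0 for fixation runs and 0.05 for
    invasion-from-rarity runs. Stabilization is declared by
    :func:`is_stable` (trailing 200-generation window means differing by
    at most 0.01, evaluated after generation ``min_generation``).
    """

    params: ModelParams
    K: int = 1
    mode: str = "microbe"
    dims: tuple[int, int] = (100, 100)
    init: tuple[str, float] = ("random", 0.05)
    seed: int = 0
    window: int = 200
    tolerance: float = 0.01
    min_generation: int = 400
    max_generation: int = 10_000
    upper_target: float = 1.0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.mode not in ("microbe", "genetic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.0 < self.upper_target <= 1.0):
            raise ValueError("upper_target must lie in (0, 1]")


@dataclass
class RunResult:
    """Outcome of one spatial run.

    ``trajectory[g]`` is the proportion of alpha after reproduction in
    generation ``g`` (index 0 is the initial configuration). ``outcome``
    is one of ``extinct``, ``fixed``, ``reached_target``, ``stabilized``,
    ``max_generations``.
    """

    trajectory: np.ndarray
    outcome: str
    final_p: float
    generations_elapsed: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "final_p": self.final_p,
            "generations_elapsed": self.generations_elapsed,
            "seed": self.seed,
        }


def init_random(
    dims: tuple[int, int], fraction: float, mode: str = "microbe", seed: int | None = 0
) -> Lattice:
    """Lattice with an exact count of alpha sites in uniform random positions.

    Exactly ``round(fraction * rows * cols)`` sites carry alpha, sampled
    without replacement; the exact-count convention removes initial-
    condition variance relative to per-site Bernoulli placement.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    rows, cols = dims
    n = rows * cols
    k = round(fraction * n)
    states = np.zeros(n, dtype=np.int8)
    if k:
        rng = np.random.default_rng(seed)
        states[rng.choice(n, size=k, replace=False)] = 1
    return Lattice(states=states.reshape(rows, cols), mode=mode)


def init_patch(dims: tuple[int, int], side: int, mode: str = "microbe") -> Lattice:
    """Lattice that is all beta except a central ``side`` x ``side`` alpha block."""
    rows, cols = dims
    if side > min(rows, cols):
        raise ValueError("patch side exceeds the grid")
    states = np.zeros((rows, cols), dtype=np.int8)
    r0 = (rows - side) // 2
    c0 = (cols - side) // 2
    states[r0 : r0 + side, c0 : c0 + side] = 1
    return Lattice(states=states, mode=mode)


def neighborhood(dims: tuple[int, int], site: tuple[int, int]) -> list[tuple[int, int]]:
    """Moore neighbors of ``site`` (0-based (row, col)), truncated at edges.

    Interior sites have 8 neighbors, non-corner edge sites 5, corners 3.
    The grid is not toroidal.
    """
    rows, cols = dims
    r, c = site
    if not (0 <= r < rows and 0 <= c < cols):
        raise ValueError(f"site {site} outside a {rows}x{cols} grid")
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols:
                out.append((rr, cc))
    return out


def run_generation(
    lattice: Lattice, params: ModelParams, K: int = 1, seed: int | None = None
) -> tuple[Lattice, float]:
    """Advance a lattice by one generation; returns the new lattice and its p.

    If ``seed`` is given the kernel RNG stream is (re)seeded first;
    otherwise the stream continues from its current state (as inside
    :func:`run_simulation`). The input lattice is left unchanged except
    that its ``payoff_sum`` and ``interaction_count`` accumulators are
    filled in for inspection.
    """
    if seed is not None:
        seed_kernel(int(seed) % _SEED_MOD)
    rows, cols = lattice.dims
    microbe = lattice.mode == "microbe"
    vt = params.VT if microbe else 1.0
    new_flat, payoff, count = generation_kernel(
        lattice.states.reshape(-1),
        rows,
        cols,
        float(params.b),
        float(params.c),
        float(params.b_g),
        float(params.c_g),
        float(params.T_alpha) if microbe else 0.0,
        float(params.T_beta) if microbe else 0.0,
        float(vt),
        int(K),
        microbe,
    )
    lattice.payoff_sum = payoff.reshape(rows, cols)
    lattice.interaction_count = count.reshape(rows, cols)
    new = Lattice(states=new_flat.reshape(rows, cols), mode=lattice.mode)
    return new, new.p


def is_stable(
    p_history,
    window: int = 200,
    tolerance: float = 0.01,
    min_generation: int = 400,
) -> bool:
    """Smoothed-p stopping rule.

    With ``pbar(k)`` the mean of p over generations (k - window, k], the
    trajectory counts as stable at its current generation g when
    g > min_generation and ``|pbar(g) - pbar(g - window)| <= tolerance``.
    Smoothing makes the rule insensitive to short-period oscillation.
    """
    p_history = np.asarray(p_history, dtype=float)
    g = len(p_history) - 1
    if g <= min_generation or g < 2 * window:
        return False
    recent = p_history[g - window + 1 : g + 1].mean()
    earlier = p_history[g - 2 * window + 1 : g - window + 1].mean()
    return abs(recent - earlier) <= tolerance


def run_simulation(config: SimConfig) -> RunResult:
    """Run one spatial simulation to an absorbing target, stabilization, or cap.

    The run stops when p reaches 0 (``extinct``), 1 (``fixed``), the
    configured ``upper_target`` if below 1 (``reached_target``), when the
    smoothed trajectory stabilizes (``stabilized``), or at
    ``max_generation`` (``max_generations``, reporting the p measured
    there). Two independent child seeds are derived from ``config.seed``:
    one for the initial placement, one for the generation kernel stream.
    """
    ss = np.random.SeedSequence(config.seed)
    s_init, s_run = (int(s.generate_state(1)[0]) % _SEED_MOD for s in ss.spawn(2))

    kind, value = config.init
    if kind == "random":
        lattice = init_random(config.dims, float(value), config.mode, seed=s_init)
    elif kind == "patch":
        lattice = init_patch(config.dims, int(value), config.mode)
    else:
        raise ValueError(f"unknown init kind {kind!r}")

    seed_kernel(s_run)
    history = [lattice.p]
    outcome = None
    gen = 0
    while True:
        p = history[-1]
        if p <= 0.0:
            outcome = "extinct"
        elif p >= 1.0:
            outcome = "fixed"
        elif config.upper_target < 1.0 and p >= config.upper_target:
            outcome = "reached_target"
        elif is_stable(history, config.window, config.tolerance, config.min_generation):
            outcome = "stabilized"
        elif gen >= config.max_generation:
            outcome = "max_generations"
        if outcome is not None:
            break
        lattice, p_new = run_generation(lattice, config.params, config.K)
        history.append(p_new)
        gen += 1

    traj = np.asarray(history)
    return RunResult(
        trajectory=traj,
        outcome=outcome,
        final_p=float(traj[-1]),
        generations_elapsed=gen,
        seed=config.seed,
    )
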