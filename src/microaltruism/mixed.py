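"""Finite-N stochastic simulator of the well-mixed model.

Serves as an independent brute-force check on the deterministic recursion
in :mod:`microaltruism.analytic`: the population is randomly divided into
pairs, a single interaction (payoff, then a horizontal-transmission draw)
occurs in each pair, and the next generation of the same size is sampled
with replacement with probability proportional to fitness (a Wright-Fisher
style realization of fitness-proportional reproduction). Each offspring
inherits its parent's post-interaction microbe with probability VT and
otherwise the microbe of a uniformly random individual from the
post-interaction parent population.

Fitness is 1 plus the interaction payoff, so it is positive throughout the
prisoner's-dilemma regime (payoffs are bounded below by -(c_g + c) > -1).
"""

from __future__ import annotations

import numpy as np

from .core import ModelParams

__all__ = ["FinitePopulation", "step", "estimate_delta_p"]


class FinitePopulation:
    """A well-mixed population of ``N`` hosts (``N`` even, for pairing).

    ``states`` is a boolean array: True marks an alpha-carrier.
    """

    def __init__(self, N: int, p0: float, rng: np.random.Generator):
        if N < 2 or N % 2:
            raise ValueError(f"population size must be even and >= 2, got {N}")
        if not (0.0 <= p0 <= 1.0):
            raise ValueError(f"initial proportion must lie in [0, 1], got {p0}")
        n_alpha = round(p0 * N)
        states = np.zeros(N, dtype=bool)
        states[:n_alpha] = True
        rng.shuffle(states)
        self.N = N
        self.states = states

    @property
    def p(self) -> float:
        return float(self.states.mean())


def step(pop: FinitePopulation, params: ModelParams, rng: np.random.Generator) -> None:
    """Advance the population by one generation, in place."""
    N = pop.N
    order = rng.permutation(N)
    half = N // 2
    first, second = order[:half], order[half:]
    a1 = pop.states[first]
    a2 = pop.states[second]

    # payoff -> fitness (1 + received benefit - own cost), before transmission
    fitness = np.empty(N)
    base = 1.0 + params.b_g - params.c_g
    fitness[first] = base + params.b * a2 - params.c * a1
    fitness[second] = base + params.b * a1 - params.c * a2
    if np.any(fitness <= 0.0):
        raise ValueError("non-positive fitness; parameters outside the valid regime")

    # horizontal transmission: independent attempts, simultaneous double
    # transmission swaps the pair's microbes (so it leaves counts unchanged)
    post = pop.states.copy()
    discord = a1 != a2
    if np.any(discord) and (params.T_alpha > 0 or params.T_beta > 0):
        n_d = int(discord.sum())
        ta_hit = rng.random(n_d) < params.T_alpha
        tb_hit = rng.random(n_d) < params.T_beta
        d1 = first[discord]
        d2 = second[discord]
        alpha_first = a1[discord]  # True where the alpha-carrier sits in `first`
        # alpha transmits alone -> both alpha; beta alone -> both beta;
        # both -> swap; neither -> unchanged
        both = ta_hit & tb_hit
        only_a = ta_hit & ~tb_hit
        only_b = tb_hit & ~ta_hit
        post[d1[only_a]] = True
        post[d2[only_a]] = True
        post[d1[only_b]] = False
        post[d2[only_b]] = False
        post[d1[both]] = ~alpha_first[both]
        post[d2[both]] = alpha_first[both]

    # fitness-proportional reproduction with replacement
    parents = rng.choice(N, size=N, p=fitness / fitness.sum())
    offspring = post[parents]
    if params.VT < 1.0:
        horizontal = rng.random(N) >= params.VT
        n_h = int(horizontal.sum())
        if n_h:
            offspring[horizontal] = post[rng.integers(0, N, size=n_h)]
    pop.states = offspring


def estimate_delta_p(
    N: int,
    p0: float,
    params: ModelParams,
    replicates: int,
    seed: int,
) -> tuple[float, float]:
    """Monte-Carlo mean and standard error of the one-generation change in p.

    Each replicate starts from an exact count ``round(p0 * N)`` of
    alpha-carriers (so the realized starting proportion is the same in
    every replicate) and runs a single generation.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates for a standard error")
    rng = np.random.default_rng(seed)
    deltas = np.empty(replicates)
    for r in range(replicates):
        pop = FinitePopulation(N, p0, rng)
        p_start = pop.p
        step(pop, params, rng)
        deltas[r] = pop.p - p_start
    mean = float(deltas.mean())
    se = float(deltas.std(ddof=1) / np.sqrt(replicates))
    return mean, se
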