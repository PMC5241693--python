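"""Deterministic recursion for the infinite, fully mixed host population.

Each generation the population is randomly divided into pairs, a single
interaction occurs in each pair (with potential horizontal transmission of
microbes), hosts reproduce in proportion to their fitness, and microbes are
transmitted vertically with fidelity ``VT``. Writing ``p`` for the
proportion of newborn hosts carrying the altruism-inducing microbe alpha and
``B = 1 + b_g - c_g`` for baseline fitness, the recursion is

    p_tilde = p + p (1 - p) (T_alpha - T_beta)                 (after interaction)
    w_bar   = B + p (b - c)                                    (mean fitness)
    p'      = VT * W + (1 - VT) * p_tilde

where ``W`` is the fitness-weighted proportion of parents whose
post-interaction microbe is alpha. The change per generation factors as

    p' - p = p (1 - p) * [ VT (b T_alpha - c (1 - T_beta)
                               - B (T_beta - T_alpha)) / w_bar
                           + (1 - VT) (T_alpha - T_beta) ]

so the sign of the bracket is the spread condition. With perfect vertical
transmission (VT = 1) and no baseline altruism the bracket reduces to the
p-independent invasion condition  b T_alpha > c (1 - T_beta) + (T_beta -
T_alpha); with equal transmission probabilities T_alpha = T_beta = T it
reduces further to  b / c > (1 - T) / T  for any VT > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import ModelParams

__all__ = [
    "Trajectory",
    "post_interaction_proportion",
    "mean_fitness",
    "next_generation_proportion",
    "spread_condition",
    "spread_margin",
    "critical_bc_ratio",
    "genetic_next_generation",
    "iterate",
]


@dataclass
class Trajectory:
    """Sequence of (generation, p) pairs produced by :func:`iterate`."""

    p: np.ndarray  # p[g] is the proportion at generation g, g = 0..len-1
    converged: bool = False

    @property
    def generations(self) -> np.ndarray:
        return np.arange(len(self.p))

    @property
    def final_p(self) -> float:
        return float(self.p[-1])

    def __len__(self) -> int:
        return len(self.p)


def _check_p(p: float) -> float:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"proportion p must lie in [0, 1], got {p}")
    return float(p)


def post_interaction_proportion(p: float, params: ModelParams) -> float:
    """Proportion of alpha-carriers after one round of paired interactions.

    Random pairing puts a fraction 2 p (1 - p) of hosts into discordant
    pairs; each such pair holds an expected ``1 + T_alpha - T_beta``
    alpha-carriers after transmission, hence

        p_tilde = p + p (1 - p) (T_alpha - T_beta).
    """
    p = _check_p(p)
    return p + p * (1.0 - p) * (params.T_alpha - params.T_beta)


def mean_fitness(p: float, params: ModelParams) -> float:
    """Population mean fitness  w_bar = 1 + b_g - c_g + p (b - c)."""
    p = _check_p(p)
    return params.baseline_fitness + p * (params.b - params.c)


def next_generation_proportion(p: float, params: ModelParams) -> float:
    """One step of the fully mixed recursion.

    A newborn alpha-carrier is either the offspring of a parent whose
    post-interaction microbe was alpha and who transmitted vertically
    (probability VT), or an offspring that drew a random microbe from the
    post-interaction parent population (probability 1 - VT, proportion
    ``p_tilde`` of which is alpha). The vertical route weights parents by
    fitness:

        f_aa = B + b - c   alpha paired with alpha (stays alpha)
        f_ab = B - c       alpha paired with beta  (stays alpha w.p. 1 - T_beta)
        f_ba = B + b       beta  paired with alpha (becomes alpha w.p. T_alpha)

        W = [p^2 f_aa + p (1-p) (f_ab (1 - T_beta) + f_ba T_alpha)] / w_bar
    """
    p = _check_p(p)
    w = mean_fitness(p, params)
    if w <= 0.0:
        raise ValueError(f"mean fitness must be positive, got {w}")
    B = params.baseline_fitness
    ta, tb = params.T_alpha, params.T_beta
    f_aa = B + params.b - params.c
    f_ab = B - params.c
    f_ba = B + params.b
    W = (p * p * f_aa + p * (1.0 - p) * (f_ab * (1.0 - tb) + f_ba * ta)) / w
    p_tilde = post_interaction_proportion(p, params)
    p_next = params.VT * W + (1.0 - params.VT) * p_tilde
    # recursion maps [0,1] into [0,1]; clip float round-off at the boundary
    return min(1.0, max(0.0, p_next))


def spread_margin(params: ModelParams, p: float) -> float:
    """Signed margin of the spread condition: (p' - p) / (p (1 - p)).

    Positive iff the proportion of alpha increases this generation.
    Closed form:

        VT (b T_alpha - c (1 - T_beta) - B (T_beta - T_alpha)) / w_bar(p)
        + (1 - VT) (T_alpha - T_beta)
    """
    p = _check_p(p)
    B = params.baseline_fitness
    ta, tb = params.T_alpha, params.T_beta
    w = mean_fitness(p, params)
    vertical = params.b * ta - params.c * (1.0 - tb) - B * (tb - ta)
    return params.VT * vertical / w + (1.0 - params.VT) * (ta - tb)


def spread_condition(params: ModelParams, p: float) -> bool:
    """True iff alpha increases in proportion from this generation to the next.

    With VT = 1 the condition is independent of ``p`` (so alpha, once
    spreading, spreads to fixation); with VT < 1 and unequal transmission
    probabilities the sign can in principle depend on ``p`` through the
    mean fitness, which is why ``p`` is an explicit argument.
    """
    return spread_margin(params, p) > 0.0


def critical_bc_ratio(
    T_alpha: float,
    T_beta: float,
    c: float,
    VT: float = 1.0,
    b_g: float = 0.0,
    c_g: float = 0.0,
) -> float:
    """Minimal benefit/cost ratio allowing alpha to invade from rarity.

    Evaluates the spread condition in the rare-invader limit p -> 0 (where
    mean fitness tends to the baseline B = 1 + b_g - c_g) and solves for
    the infimum b/c at which it first holds. Returns ``math.inf`` when no
    finite benefit satisfies the condition (e.g. T_alpha = 0: altruism
    cannot evolve without horizontal transmission of alpha) and ``0.0``
    when the condition holds for every positive benefit (possible when
    T_alpha > T_beta and the transmission advantage alone suffices).

    With T_alpha = T_beta = T this reduces to (1 - T) / T for any VT > 0.
    """
    if c <= 0.0:
        raise ValueError("cost c must be positive to define a b/c ratio")
    B = 1.0 + b_g - c_g
    if B <= 0.0:
        raise ValueError("baseline fitness 1 + b_g - c_g must be positive")
    # condition at p -> 0:  coeff * b + const0 > 0
    coeff = VT * T_alpha / B
    const0 = (
        VT * (-c * (1.0 - T_beta) - B * (T_beta - T_alpha)) / B
        + (1.0 - VT) * (T_alpha - T_beta)
    )
    if coeff <= 0.0:
        return 0.0 if const0 > 0.0 else math.inf
    b_star = -const0 / coeff
    return max(b_star / c, 0.0)


def genetic_next_generation(p: float, b_g_allele: float, c_g_allele: float) -> float:
    """One generation of the host-gene control model.

    Hosts carry an altruism allele A (cost ``c_g_allele``, partner benefit
    ``b_g_allele``) or a neutral allele E; there is no horizontal
    transmission and vertical transmission is perfect. The recursion

        p' = p (1 - c_g + p b_g) / (1 + p b_g - p c_g)

    satisfies p' < p for every p in (0, 1) whenever c_g > 0: genetically
    encoded altruism cannot evolve in a fully mixed population.
    """
    p = _check_p(p)
    if not (0.0 < c_g_allele < 1.0):
        raise ValueError(f"allele cost must satisfy 0 < c_g < 1, got {c_g_allele}")
    if b_g_allele <= c_g_allele:
        raise ValueError("allele benefit must exceed its cost (b_g > c_g)")
    denom = 1.0 + p * b_g_allele - p * c_g_allele
    if denom <= 0.0:
        raise ValueError("mean fitness must be positive")
    return p * (1.0 - c_g_allele + p * b_g_allele) / denom


def iterate(
    p0: float,
    params: ModelParams | None,
    generations: int,
    *,
    genetic: tuple[float, float] | None = None,
    tol: float = 1e-12,
) -> Trajectory:
    """Iterate the recursion for at most ``generations`` steps.

    Parameters
    ----------
    p0
        Initial proportion of alpha-carriers (or of allele A).
    params
        Microbe-model parameters; ignored when ``genetic`` is given.
    generations
        Maximum number of steps (>= 1).
    genetic
        If given, a ``(b_g_allele, c_g_allele)`` pair selecting the
        host-gene control recursion instead of the microbe recursion.
    tol
        Convergence is declared when ``|p' - p| < tol``; fixed points are
        found by iteration, which is exact enough for this one-dimensional,
        monotone recursion.
    """
    if generations < 1:
        raise ValueError("need at least one generation")
    p = _check_p(p0)
    out = [p]
    converged = False
    for _ in range(generations):
        if genetic is not None:
            p_next = genetic_next_generation(p, *genetic)
        else:
            p_next = next_generation_proportion(p, params)
        out.append(p_next)
        if abs(p_next - p) < tol:
            converged = True
            p = p_next
            break
        p = p_next
    return Trajectory(p=np.asarray(out), converged=converged)


def threshold_table(
    T_alpha_values,
    T_beta_values,
    c_values,
    VT_values,
    b_g: float = 0.0,
    c_g: float = 0.0,
):
    """Critical b/c ratios over a parameter grid, as a tidy DataFrame.

    Columns: T_alpha, T_beta, c, VT, b_g, c_g, critical_bc. The ratio is
    monotone non-increasing in T_alpha at fixed other parameters.
    """
    import pandas as pd

    rows = []
    for ta in T_alpha_values:
        for tb in T_beta_values:
            for c in c_values:
                for vt in VT_values:
                    rows.append(
                        {
                            "T_alpha": ta,
                            "T_beta": tb,
                            "c": c,
                            "VT": vt,
                            "b_g": b_g,
                            "c_g": c_g,
                            "critical_bc": critical_bc_ratio(ta, tb, c, vt, b_g, c_g),
                        }
                    )
    return pd.DataFrame(rows)
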