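"""Shared parameter types, the pairwise payoff rule, and per-interaction
horizontal-transmission outcomes.

The model considers hosts that each carry exactly one of two microbe types:
``ALPHA`` microbes manipulate their host into acting altruistically, while
``BETA`` microbes leave behaviour unchanged. In a genetic control mode the
same roles are played by host alleles ``A`` (altruist) and ``E`` (neutral),
which are never transmitted horizontally.

Interactions are pairwise with a prisoner's-dilemma payoff: an altruistic
actor pays a cost ``c`` and confers a benefit ``b > c`` on its partner, on
top of a population-wide baseline level of altruism (``b_g``, ``c_g``)
shared by every host. Payoffs are always computed from the pair's states
*before* any horizontal transmission in that interaction: behaviour is
attributed to the resident microbe.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class Carrier(enum.IntEnum):
    """State of a single host: microbe type or allele."""

    BETA = 0   # non-manipulating microbe
    ALPHA = 1  # altruism-inducing microbe
    E = 2      # neutral allele (genetic mode)
    A = 3      # altruism allele (genetic mode)

    @property
    def is_altruist(self) -> bool:
        return self in (Carrier.ALPHA, Carrier.A)

    @property
    def is_microbe(self) -> bool:
        return self in (Carrier.ALPHA, Carrier.BETA)


@dataclass(frozen=True)
class ModelParams:
    """Evolutionary parameters of the microbe-induced altruism model.

    Parameters
    ----------
    b, c
        Benefit conferred on the partner and cost paid by the actor for the
        microbe-induced altruistic act (dimensionless payoff units).
        The prisoner's-dilemma regime of interest has ``b > c``; requires
        ``0 <= c < 1`` and ``b >= 0`` (threshold analyses evaluate the
        boundary ``b = c`` and the neutral case ``b = c = 0``).
    b_g, c_g
        Baseline benefit/cost paid by *every* host regardless of microbe,
        modelling a genetically fixed background level of altruism. A
        uniform cost of microbe carriage folds into ``c_g``; a differential
        cost folds into ``c``. Requires ``1 + b_g - c_g > 0`` so that mean
        fitness stays positive.
    T_alpha, T_beta
        Per-interaction probability that the alpha (resp. beta) microbe is
        transmitted to the interacting partner and establishes, replacing
        the resident microbe. Both in [0, 1].
    VT
        Vertical-transmission fidelity: probability an offspring inherits
        its parent's microbe rather than a random microbe from the parent
        population (or neighbourhood, in the spatial model). In [0, 1].
    """

    b: float
    c: float
    T_alpha: float = 0.0
    T_beta: float = 0.0
    VT: float = 1.0
    b_g: float = 0.0
    c_g: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.c < 1.0):
            raise ValueError(f"cost c must satisfy 0 <= c < 1, got {self.c}")
        if self.b < 0.0:
            raise ValueError(f"benefit b must be >= 0, got {self.b}")
        for name in ("T_alpha", "T_beta", "VT"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.c_g < 0:
            raise ValueError(f"c_g must be >= 0, got {self.c_g}")
        if 1.0 + self.b_g - self.c_g <= 0.0:
            raise ValueError("baseline fitness 1 + b_g - c_g must be positive")

    @property
    def baseline_fitness(self) -> float:
        """Fitness of a host in the absence of any alpha microbe: 1 + b_g - c_g."""
        return 1.0 + self.b_g - self.c_g


def pair_payoffs(
    state_i: Carrier, state_j: Carrier, params: ModelParams
) -> tuple[float, float]:
    """Payoffs of a single pairwise interaction, before any transmission.

    Each participant pays its own cost (``c_g``, plus ``c`` if it is an
    altruist) and receives the benefit generated by its partner (``b_g``,
    plus ``b`` if the partner is an altruist). The rule is symmetric in the
    two roles; which host initiated the interaction is irrelevant.

    Returns
    -------
    (payoff_i, payoff_j)
    """
    state_i = Carrier(state_i)
    state_j = Carrier(state_j)
    if state_i.is_microbe != state_j.is_microbe:
        raise ValueError("cannot mix microbe-mode and genetic-mode states in one pair")
    pay_i = (params.b_g + params.b * state_j.is_altruist) - (
        params.c_g + params.c * state_i.is_altruist
    )
    pay_j = (params.b_g + params.b * state_i.is_altruist) - (
        params.c_g + params.c * state_j.is_altruist
    )
    return pay_i, pay_j


def transmission_distribution(
    state_i: Carrier, state_j: Carrier, params: ModelParams
) -> dict[tuple[Carrier, Carrier], float]:
    """Distribution over post-interaction states after horizontal transmission.

    Transmission-and-establishment of one microbe is independent of the
    other; when both succeed they occur simultaneously, so a discordant
    pair swaps microbes rather than collapsing to one type. Concordant
    pairs are unchanged with probability 1.

    For a discordant pair (alpha at ``i``, beta at ``j``)::

        (alpha, alpha)  with prob T_alpha * (1 - T_beta)
        (beta,  beta)   with prob T_beta  * (1 - T_alpha)
        (beta,  alpha)  with prob T_alpha * T_beta          (swap)
        (alpha, beta)   with prob (1 - T_alpha) * (1 - T_beta)

    Returns a dict mapping ``(post_i, post_j)`` to probability; zero-mass
    outcomes are included for discordant pairs so the support is explicit.
    """
    state_i = Carrier(state_i)
    state_j = Carrier(state_j)
    if not (state_i.is_microbe and state_j.is_microbe):
        raise ValueError("horizontal transmission applies to microbe-mode states only")
    if state_i == state_j:
        return {(state_i, state_j): 1.0}
    ta, tb = params.T_alpha, params.T_beta
    a, b_ = Carrier.ALPHA, Carrier.BETA
    if state_i == a:  # alpha at i, beta at j
        return {
            (a, a): ta * (1 - tb),
            (b_, b_): tb * (1 - ta),
            (b_, a): ta * tb,
            (a, b_): (1 - ta) * (1 - tb),
        }
    # beta at i, alpha at j: mirror image
    return {
        (a, a): ta * (1 - tb),
        (b_, b_): tb * (1 - ta),
        (a, b_): ta * tb,
        (b_, a): (1 - ta) * (1 - tb),
    }
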