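"""Numba kernels for the lattice simulator.

All stochastic draws inside a run consume numba's global legacy RNG stream
in a fixed, documented order (see :func:`generation_kernel`), so runs are
bit-reproducible given the seed passed to :func:`seed_kernel`. The genetic
control mode consumes exactly the same stream as microbe mode with
``VT = 1`` and ``T_alpha = T_beta = 0``: transmission and vertical-
transmission draws are skipped whenever they cannot change any state, which
makes the two modes trajectory-identical under shared seeds.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["seed_kernel", "generation_kernel"]


@njit(cache=True)
def seed_kernel(seed: int) -> None:
    """Seed the numba-internal RNG stream used by the lattice kernel."""
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _neighbors(site, rows, cols, out):
    """Moore neighborhood truncated at the lattice edges (non-toroidal).

    Writes flat neighbor indices into ``out`` in row-major scan order and
    returns their count: 8 in the interior, 5 on edges, 3 in corners.
    """
    r = site // cols
    c = site % cols
    m = 0
    for dr in range(-1, 2):
        rr = r + dr
        if rr < 0 or rr >= rows:
            continue
        for dc in range(-1, 2):
            if dr == 0 and dc == 0:
                continue
            cc = c + dc
            if cc < 0 or cc >= cols:
                continue
            out[m] = rr * cols + cc
            m += 1
    return m


@njit(cache=True)
def generation_kernel(states, rows, cols, b, c, bg, cg, Ta, Tb, VT, K, microbe):
    """One full generation; returns (new_states, payoff_sum, interaction_count).

    RNG stream order per generation:
      1. for each of the K interaction sweeps: one permutation of all sites,
         then per initiator one neighbor draw, then (microbe mode, discordant
         pair, some transmission possible) two uniforms for the independent
         transmission attempts;
      2. reproduction, sites in row-major order: one tie-break draw among the
         co-maximal-fitness members of {site} + neighbors, then (microbe
         mode, VT < 1) one uniform for the vertical-transmission event and,
         on failure, one draw of a random neighborhood member.

    ``states`` is a flat int8 array (1 = alpha/altruist allele, 0 = beta/
    neutral allele); it is not modified.
    """
    n = rows * cols
    st = states.copy()
    payoff = np.zeros(n, dtype=np.float64)
    count = np.zeros(n, dtype=np.int64)
    nbuf = np.empty(8, dtype=np.int64)
    can_transmit = microbe and (Ta > 0.0 or Tb > 0.0)

    for _ in range(K):
        order = np.random.permutation(n)
        for t in range(n):
            i = order[t]
            m = _neighbors(i, rows, cols, nbuf)
            j = nbuf[np.random.randint(m)]
            ai = st[i]
            aj = st[j]
            payoff[i] += (bg + b * aj) - (cg + c * ai)
            payoff[j] += (bg + b * ai) - (cg + c * aj)
            count[i] += 1
            count[j] += 1
            if can_transmit and ai != aj:
                ta_hit = np.random.random() < Ta
                tb_hit = np.random.random() < Tb
                if ta_hit and tb_hit:  # simultaneous: swap microbes
                    st[i] = 1 - ai
                    st[j] = 1 - aj
                elif ta_hit:
                    st[i] = 1
                    st[j] = 1
                elif tb_hit:
                    st[i] = 0
                    st[j] = 0

    # every site initiates K interactions, so count >= K >= 1 everywhere
    fitness = payoff / count

    new_states = np.empty(n, dtype=np.int8)
    cand = np.empty(9, dtype=np.int64)
    ties = np.empty(9, dtype=np.int64)
    for site in range(n):
        m = _neighbors(site, rows, cols, cand)
        cand[m] = site
        m += 1
        best = -1.0e300
        ntie = 0
        for k in range(m):
            f = fitness[cand[k]]
            if f > best:
                best = f
                ties[0] = cand[k]
                ntie = 1
            elif f == best:
                ties[ntie] = cand[k]
                ntie += 1
        parent = ties[np.random.randint(ntie)]
        new_states[site] = st[parent]
        if microbe and VT < 1.0:
            if np.random.random() >= VT:
                # offspring draws the microbe of a random individual from
                # the neighborhood of its site in the parent generation
                new_states[site] = st[cand[np.random.randint(m)]]

    return new_states, payoff, count
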