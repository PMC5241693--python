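# microaltruism

Models of microbe-induced host altruism: can a microbe that manipulates its
host into helping other hosts be favoured by selection, even when altruism
encoded in the host's own genes cannot evolve?

Every host carries one of two microbe types. Type α drives its host to act
altruistically in pairwise prisoner's-dilemma interactions — the actor pays
a fitness cost *c* (0 < *c* < 1), the partner gains a benefit *b* > *c* —
while type β leaves behaviour unchanged. During an interaction the microbes
can transmit horizontally: with probability *T*<sub>α</sub> the α microbe
establishes in the partner (replacing its β), with probability
*T*<sub>β</sub> the reverse, independently, and a simultaneous double
transmission swaps the pair's microbes. At reproduction an offspring
inherits its parent's microbe with probability VT (vertical transmission)
and otherwise picks up a random microbe from the parent population. The key
effect is that an α-manipulated host helps a partner that, with probability
*T*<sub>α</sub>, now carries relatives of the manipulating microbe — kin
selection among the microbes, not the hosts.

The package provides:

- **`microaltruism.analytic`** — the deterministic recursion for an
  infinite, fully mixed population, with the closed-form spread condition

  VT·(b·T<sub>α</sub> − c·(1 − T<sub>β</sub>) − (1 + b<sub>g</sub> − c<sub>g</sub>)·(T<sub>β</sub> − T<sub>α</sub>))/w̄ + (1 − VT)·(T<sub>α</sub> − T<sub>β</sub>) > 0,

  the critical b/c solver (for equal transmission T the threshold is
  (1 − T)/T for any VT > 0), and the genetic-altruism control recursion, in
  which altruism always declines.
- **`microaltruism.mixed`** — a finite-N stochastic well-mixed simulator
  used as a brute-force cross-check on the recursion.
- **`microaltruism.spatial`** — an agent-based simulator on a non-toroidal
  100×100 lattice: K interactions per host per generation, in-interaction
  horizontal transmission, Nowak–May fittest-neighbour reproduction,
  imperfect vertical transmission, a genetic-allele control mode, and a
  smoothed-trajectory stopping rule.
- **`microaltruism.experiments`** — reproducible drivers for threshold
  tables, lattice sweeps over (T, b/c), and invasion-from-rarity
  probability estimation with Wilson confidence intervals.

## Worked example

```python
>>> from microaltruism import ModelParams, critical_bc_ratio, iterate, SimConfig, run_simulation
>>> critical_bc_ratio(T_alpha=0.1, T_beta=0.1, c=0.05)
9.0
```

With equal transmission probability T = 0.1 the altruism-inducing microbe
invades whenever b/c exceeds (1 − 0.1)/0.1 = 9. At b/c = 20 it sweeps a
fully mixed population from a 5% start:

```python
>>> params = ModelParams(b=1.0, c=0.05, T_alpha=0.1, T_beta=0.1, VT=1.0)
>>> traj = iterate(0.05, params, 10_000)
>>> len(traj) - 1, round(traj.final_p, 6)
(896, 1.0)
```

The proportion of α-carriers climbs 0.05 → 0.35 → 0.77 → 0.98 over the
first 200 generations and converges to fixation, because with VT = 1 the
spread condition does not depend on the current proportion. The same
parameters on the lattice give a stable polymorphism instead — spatial
clustering lets free-riding β-hosts persist at the boundaries of altruist
clusters:

```python
>>> res = run_simulation(SimConfig(params=params, K=1, seed=1))
>>> res.outcome, round(res.final_p, 4), res.generations_elapsed
('stabilized', 0.3788, 411)
```

i.e. the run stopped at generation 411 with 37.9% of the 10,000 sites
carrying α, the trajectory's 200-generation smoothed mean having changed by
less than 0.01. In the genetic control mode (`mode="genetic"`), where the
altruism allele cannot transmit horizontally, the same setup always ends
with `outcome='extinct'`.

A command-line interface mirrors the library drivers:

```sh
microaltruism simulate --ta 0.1 --tb 0.1 --b 1.0 --c 0.05 --seed 1
microaltruism thresholds --out thresholds.csv
microaltruism sweep --mode genetic --replicates 30 --out gen_column.csv
microaltruism invasion --t 0 --t 0.1 --t 0.5 --bc 20 --out invasion.csv
```

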