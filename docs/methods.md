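# Methods

## Model

A population of asexual hosts, each carrying exactly one of two microbe
types. Type α manipulates its host into an altruistic act during every
pairwise interaction: the actor pays cost *c* (0 < *c* < 1) and the partner
receives benefit *b* > *c* (prisoner's-dilemma regime). Type β is
behaviourally inert. A shared genetic background can add a baseline level
of altruism: every host pays *c*<sub>g</sub> and every partner receives
*b*<sub>g</sub>, so an α-host pays *c*<sub>g</sub> + *c* while a β-host
pays only *c*<sub>g</sub>. Baseline fitness is B = 1 + *b*<sub>g</sub> −
*c*<sub>g</sub>, required positive. A uniform cost of carrying microbes
folds into *c*<sub>g</sub>; a cost differential between microbe types folds
into *c*.

Within one interaction the payoff is computed first, from both hosts'
current microbes; horizontal transmission is applied second. Transmission
and establishment of each microbe is an independent Bernoulli event
(probabilities *T*<sub>α</sub>, *T*<sub>β</sub>); when both succeed they
occur simultaneously, i.e. a discordant pair swaps microbes. A sequential
implementation would annihilate one lineage and break the stated
independence; the expected number of α-carriers after a discordant
interaction is 1 + *T*<sub>α</sub> − *T*<sub>β</sub> either way.

## Fully mixed recursion

With *p* the proportion of newborn α-carriers, random pairing gives pair
frequencies *p*², 2*p*(1−*p*), (1−*p*)². After interactions,

  p̃ = p + p(1−p)(T_α − T_β),   w̄ = B + p(b − c).

Reproduction is fitness-proportional; vertical transmission succeeds with
probability VT, otherwise the offspring draws a uniformly random microbe
from the **post-interaction** parent population (proportion p̃, not
fitness-weighted — the non-vertical route is a blind environmental pickup,
so weighting it by parental fitness would smuggle selection into a channel
the model defines as random). The next generation is

  p' = VT·W + (1−VT)·p̃,
  W = [p²·f_aa + p(1−p)·(f_ab·(1−T_β) + f_ba·T_α)] / w̄,

with f_aa = B+b−c, f_ab = B−c, f_ba = B+b the fitnesses of an α paired with
α, an α paired with β (remains α with probability 1−T_β), and a β paired
with α (becomes α with probability T_α). The change per generation factors
exactly as

  p' − p = p(1−p)·[ VT·(b·T_α − c·(1−T_β) − B·(T_β−T_α))/w̄ + (1−VT)·(T_α−T_β) ],

so the bracket (`spread_margin`) decides spread. Useful reductions, each
verified by tests against the recursion itself and the finite-N simulator:

- VT = 1, B = 1: b·T_α > c·(1−T_β) + (T_β−T_α), independent of *p* — spread
  implies fixation.
- T_α = T_β = T, B = 1: b/c > (1−T)/T for **any** VT > 0 (the VT terms
  cancel), giving thresholds 9, 99, 999 at T = 0.1, 0.01, 0.001.
- T_α = 0: the margin is strictly negative for c > 0 — no horizontal
  transmission, no microbial altruism; likewise the genetic control
  recursion p' = p(1−c_g+p·b_g)/(1+p·b_g−p·c_g) declines for every interior
  p when c_g > 0.

`critical_bc_ratio` solves the bracket for b in the rare-invader limit
p → 0 (w̄ → B). With VT < 1 and T_α ≠ T_β the sign of p'−p can in principle
depend on p through w̄; the p → 0 convention defines the reported invasion
threshold, and `spread_condition(params, p)` is exposed for p-grid
diagnostics. `math.inf` is the sentinel for "no finite threshold" (never an
exception); 0.0 means any positive benefit suffices. Fixed points of the
recursion are found by plain iteration (convergence |p'−p| < 1e−12 or a
generation cap): the map is one-dimensional, monotone between fixed points,
and cheap, so root-finding machinery would add nothing.

Parameter validation deliberately admits b < c and b = c = 0: threshold
analyses evaluate the boundary b = c, and the neutral case is the drift
control for the simulators. The dilemma regime is documentation, not a
hard constraint.

## Finite-N well-mixed simulator

An independent check, not a second implementation of the recursion: N hosts
(N even) are randomly perfectly matched, each pair gets payoff then a
transmission draw, and the next generation is a multinomial
(Wright–Fisher-style) sample of N parents with probability proportional to
fitness 1 + payoff (positive throughout the admissible range). Vertical
transmission as above, drawing the non-vertical microbe from a uniformly
random post-interaction individual. As N → ∞ its one-step mean change
converges to the recursion; the suite checks agreement within 3 standard
errors at N = 10⁵ over a 20-point grid spanning spread, decline, threshold
(b/c exactly 9 gives zero drift), unequal-T and imperfect-VT regimes, and
checks the neutral martingale (b = c = 0, equal T).

## Lattice simulator

A rows×cols grid (default 100×100), every site occupied, Moore
neighbourhoods truncated at the edges (8 interior / 5 edge / 3 corner
neighbours; not toroidal). A generation is:

1. **Interactions** — K sweeps; each sweep draws a fresh uniform permutation
   of all sites, and each initiator interacts with one uniformly chosen
   neighbour. Both parties accumulate payoff and an interaction count
   (every host initiates K times and may be chosen extra times as partner;
   total count is exactly 2·K·sites). In microbe mode a discordant pair
   then takes a transmission draw, and the recipient's new microbe governs
   its behaviour in later interactions of the same generation — with one
   microbe per host there is no other state it could act from.
2. **Fitness** — accumulated payoff divided by the individual's own
   interaction count. No +1 baseline is added: reproduction selects by
   argmax, which is invariant to additive constants.
3. **Reproduction** — each new-grid site copies the maximal-fitness host
   among the site and its neighbours, ties broken uniformly (ties are
   common, e.g. all-zero neighbourhoods, so the tie-break is part of the
   documented RNG stream). The parent's end-of-generation (post-
   transmission) microbe is copied: a parent transmits what it currently
   carries.
4. **Vertical transmission** (microbe mode, VT < 1) — with probability
   1−VT the offspring instead takes the microbe of a uniformly random
   member of {site} ∪ neighbours in the parent generation, the same
   neighbourhood reproduction uses. The draw is uniform, not
   fitness-weighted.

Genetic mode is identical with alleles instead of microbes, VT pinned to 1
and no transmission step. Draws that cannot change any state (transmission
when T_α = T_β = 0 or the pair is concordant; the VT event when VT = 1) are
skipped rather than burned, which makes microbe mode with VT = 1, T = 0 and
genetic mode consume byte-identical RNG streams — the suite asserts exactly
identical trajectories for 20 shared seeds, turning a statistical
equivalence into a deterministic one.

The per-generation loop is a numba kernel over flat arrays; one seeded
global stream per run is consumed in the fixed order documented in
`_kernels.py`. Initial placement uses a separate child seed of the run
seed: "5% of sites" is an exact count sampled without replacement, and the
patch initializer places a central side×side block (rows/cols 50–51,
1-based, on the default grid).

**Stopping.** p (measured after reproduction) hitting 0 or 1 is absorbing;
invasion runs also stop at the 0.05 target. Otherwise the run stops once
g > 400 and the two adjacent trailing 200-generation window means of p
differ by at most 0.01 (≤, fixed for determinism; the smoothing makes the
rule blind to short-period oscillation but sensitive to slow ramps —
0.001/generation moves the windows 0.2 apart). Runs are capped at 10,000
generations and report the p measured there.

## Experiment drivers and problem sizes

Per-replicate seeds derive from `SeedSequence([base_seed, cell_index,
replicate])`, so every cell is independently reproducible and results are
bit-identical across repeated calls. Invasion probabilities carry Wilson
score intervals, the appropriate interval in the small-probability regime.
Sweep outputs always record the replicate count used.

Default scales are sized for a desk machine and recorded in the outputs:
sweeps use 30 replicates per cell on the full 100×100 grid over an explicit
list of (T, b/c) values; invasion estimates default to 1,000 replicates
per point, with the no-transmission neutral-bound check in the suite using
5,000 runs and a one-sided binomial test at the 4/10,000 neutral-fixation
bound (4 α-sites among 10⁴). Larger replicate counts are a flag away.

## What the simulations do and do not show

The generators emulate the model's own idealizations: infinite or
well-mixed populations, one microbe per host, constant payoffs, no
mutation, no host resistance, interactions that always permit transmission.
Passing tests therefore validate the implementation of this model, not the
biology of any particular host–microbiome system; in particular stable
lattice polymorphisms here arise purely from the interplay of clustering,
free-riding at cluster boundaries, and transmission.

On the lattice with K = 1 and VT = 1, altruism survives essentially where
the analytic line predicts at low T (e.g. extinction at T = 0.01 for b/c
up to ~300), fixes well above the line at high T (T = 0.5, threshold 1),
and at intermediate T shows a broad stable-polymorphism band whose
lower edge sits somewhat below the fully mixed threshold (at T = 0.1
survival begins between b/c = 2 and 3, against the mixed-model 9) —
spatial clustering aids rare altruists beyond what the fully mixed
analysis grants, while boundary free-riding prevents full fixation there.
The drift control (b = c = 0, equal T) reproduces survival at the initial
frequency (mean final p 0.049 vs 0.05 at 5% occupancy), showing the
update scheme is unbiased.

## Known limitations

- One microbe type per host; no within-host microbiome diversity or
  continuous altruism levels.
- No simultaneous host-gene × microbe polymorphism (the two modes are
  alternatives, not co-circulating).
- The lattice kernel's RNG is numba's global legacy stream: runs are
  reproducible but not parallelizable within one process.
- Invasion thresholds for VT < 1 with unequal T are defined at p → 0; a
  different reference p can move the reported threshold when the condition
  depends on p.
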