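# nidm — networking during infectious diseases

An agent-based simulator of social-network rewiring under epidemic risk.
Sixty agents play a round-based networking game in which maintaining a good
social position earns points, while an SIR-type disease spreads over the
very ties that earn them. Each round has four stages: (1) every agent is
offered twelve other nodes and decides which existing ties to keep or
dissolve and which new ties to propose, (2) proposal recipients accept or
decline, (3) point rewards are paid, (4) the disease is transmitted and
infection clocks advance. The game ends when no infectious node remains, or
after 20 rounds.

The package is aimed at researchers studying the feedback loop between
avoidance behavior, network structure, and epidemic size — it reproduces a
published experimental design (2×2: low/high network clustering × random/
assortative mixing by risk attitude) with simulated, myopically optimizing
agents, and exports participant/network/decision data in analysis-ready CSV
form.

## Model

Per round, agent *i* with *t* ties, local triad proportion *x* (the share
of its neighbor pairs that are themselves connected), and disease state *s*
earns

```
U_i = b1·t + b2·(1 − 2|x − α| / max(α, 1−α)) − (c1·t + c2·t²) − σ·[s = I]
```

scaled by 41.88 into display points. Under the defaults (b1 = 1, c1 = 0.2,
c2 = 0.067, b2 = 0.5, σ = 0.34) six ties are optimal (100 points), the triad
bonus peaks at the condition's preferred clustering α (21 points at x = α),
and an infected round costs 14 points. A susceptible node with k infectious
neighbors is infected with probability

```
π = 1 − (1 − γ)^k,        γ = 0.15
```

and recovers permanently after τ = 4 infected rounds. For decisions, agents
replace the objective infection cost σ with the *perceived* cost
`σ^r · π^(2−r)`, where r ∈ (0, 2) is a risk aversion score elicited by a
five-step staircase task (1.0 = risk-neutral). Each offered tie change is
evaluated myopically by its one-round perceived-utility delta; dissolution
is unilateral, creation requires both sides to gain.

## Worked example

```python
import numpy as np
from nidm import (Condition, Clustering, Mixing, ParamSet,
                  run_game, sample_risk_scores)

scores = sample_risk_scores(60, np.random.default_rng(0))
cond = Condition(Clustering.LO, Mixing.RA, seed=3)
res = run_game(cond, scores, ParamSet(), seed=3)
print(res.rounds_played, round(res.final_size, 3), res.index_case)
```

prints

```
7 0.05 53
```

— the epidemic started at node 53 (the most structurally and attitudinally
average node), infected 3 of 60 nodes (final size 0.05: the index case plus
two secondary cases), and burned out in round 7, ending the game early.
The same call with `seed=0` ends at round 20 with final size 0.267:
outcomes are strongly bimodal, as expected for a stochastic SIR process
near its outbreak threshold.

A full experimental batch (48 sessions × 2 games, 24 per condition):

```python
from nidm import run_batch, write_outputs
results = run_batch(ParamSet(), master_seed=1)
write_outputs(results, "outdir")
```

or from the shell:

```
nidm simulate --seed 1 --out outdir
nidm generate-network --setting HI --seed 1 --out hi.csv --graphml
nidm staircase --choices 01011
nidm analyze --in outdir --report report.json
```

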