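# phagecoi

Biophysical modelling of lysogeny caused by phage coinfection in microbial
communities.

Temperate phages choose between lysing their host and integrating as a
prophage, and coinfection — two or more phages infecting the same cell
within the decision window — is a well-characterized trigger of lysogeny.
`phagecoi` quantifies how often coinfection-driven lysogenization happens in
real communities, from the oceans to the mammalian gut, using only measurable
physical traits: phage and bacterial concentrations, adsorption rate
constants, and lysogenic commitment times.

The core model: the mean number of phages infecting one cell within the
commitment time τ is

    COI = Pᵢ · α · τ

(phages/ml × ml/h × h, dimensionless), and with Poisson-distributed
infection counts the probability of forming a lysogen (≥ 2 infections) is

    p_lys = 1 − e^(−COI) − COI·e^(−COI)

Around this sit the calibration procedures of the supporting meta-analysis
(phage-vs-bacteria abundance power law, Hill-Langmuir cooperativity fits
with order selection, rank-abundance curves, trait comparisons), a
vectorized stochastic community simulator (Latin hypercube sampling of
trait ranges, 100 rank-matched phage-host pairs per community), conditioned
summary statistics, and synthetic-data generators that make the whole
pipeline testable offline. See `docs/methods.md` for the model's
assumptions and parameter choices.

## Worked example

```python
from phagecoi import (coi_from_ratio, lysogeny_probability, gut_config,
                      simulate_ecosystem, condition_on_lysogeny)

# lambda-like lab conditions: alpha = 5.6e-7 ml/h, tau = 0.1 h, B = 5e8 cells/ml
coi = coi_from_ratio(1.0, 5e8, 5.6e-7, 0.1)
print(coi, lysogeny_probability(2.0))
# 28.0 0.5939941502901619

# 100,000 stochastic gut communities
gut = simulate_ecosystem(gut_config(), 100_000, master_seed=2)
high = condition_on_lysogeny(gut, 25)
print(f"{100 * len(high) / len(gut):.1f}% of gut communities reach >=25% lysogeny;"
      f" median {high.percent_lysogeny.median():.1f}%")
# 13.7% of gut communities reach >=25% lysogeny; median 37.7%
```

At the lambda reference point a phage-to-bacterium ratio of 1 already means
28 expected infections per cell, and COI = 2 gives a ~59% chance of
lysogenization. In the simulated gut ecosystem a substantial minority of
communities — those with high densities, fast adsorption and long
commitment times — are dominated by coinfection-driven lysogeny, while the
marine runs stay mostly below 10% lysogeny.

Narrative scripts in `examples/` walk through each capability:

- `examples/coinfection_basics.py` — COI arithmetic, the lysogeny
  probability, parameter scans across bacterial densities;
- `examples/hill_calibration.py` — Hill order selection on a synthetic MOI
  experiment, power-law fitting, marine-vs-gut trait comparison;
- `examples/community_simulation.py` — the full two-ecosystem simulation
  with lysogeny distributions, conditioned summaries, rank contributions,
  VMR and daily lysogen production.

A thin CLI wraps the same library calls:

```bash
phagecoi simulate --ecosystem gut --n-communities 100000 --seed 2 --out gut.csv
phagecoi summarize gut.csv --threshold 1 --threshold 25 --out-dir summaries/
phagecoi fixtures --kind moi --seed 4 --out moi.csv
phagecoi fit --kind hill --data moi.csv --out hill.json
```

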