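# foodsust

Multi-dimensional sustainability assessment of food systems, as a tested,
reusable Python pipeline. It is aimed at researchers and practitioners who
rate food systems on ordinal indicator frameworks — agroecologists,
food-policy analysts, sustainability-assessment teams — and who need the
arithmetic behind such assessments to be explicit, reproducible and unit
tested.

## The assessment model

A *food system* (the network of actors and activities from production
through consumption) is scored on a framework of **56 indicators** spanning
five sustainability dimensions — food security (9 indicators), right to
food (14), poverty and inequality (12), environmental performance (8), and
social-ecological resilience (13) — each indicator also tagged with a
value-chain activity: production, processing/storage, retail/trade,
consumption, or transversal.

Every indicator is rated on an ordinal five-point Likert scale,
`0` (very low / undesirable) to `4` (very high / desirable). Quantitative
measurements are mapped linearly through an attainment fraction
`p ∈ [0, 1]` — against an official benchmark (e.g. minimum wage) or against
the maximum value observed in the study context — with
`score = round-half-up(4·p)`. Because the scale is ordinal, aggregation
uses medians, not means, of raw scores:

- **dimension median** `m_d` = median of a dimension's non-missing
  indicator scores for one food system;
- **overall score** = arithmetic mean of the five dimension medians,
  `(1/5) Σ_d m_d ∈ [0, 4]`;
- **activity profile** = median per activity category, with the cumulative
  score `Σ_a m_a ∈ [0, 20]` and per-activity quartiles.

Two cross-system analyses identify *key levers* — indicators that drive
sustainability across food systems:

- **deviation frequencies**: each indicator is counted, system by system,
  as scoring below / above / equal to that system's reference median (the
  median over all its indicator scores); indicators below the reference in
  most systems are shared weak points;
- **ordinal PCA**: pairwise polychoric correlations (two-step maximum
  likelihood under a latent bivariate-normal threshold model, with
  PSD repair by eigenvalue clipping) feed a principal component analysis;
  components are retained by the Kaiser criterion (eigenvalue > 1, capped
  at n_observations − 1) and each component's influential indicators are
  those with |loading| > 0.45.

The environmental dimension uses the **Agroecosystem Service Capacity
index**: for land-cover class *i* with area share `A_i`, service count
`N_i` (out of a 23-service catalogue) and mean provision strength `S_i`,

```
ASC_i = ((S_i + N_i) / 2) · A_i,      ASCI = Σ_i ASC_i
```

and the resilience dimension uses Shannon diversity `H = −Σ p ln p` over
crop/breed counts.

## Worked example

```python
from foodsust import load_default_registry, assess_all
from foodsust.synthetic_data import default_archetypes, simulate_scores
from foodsust.deviation import deviation_table, rank_levers

registry = load_default_registry()
matrix = simulate_scores(default_archetypes(), registry, seed=42)
print(assess_all(matrix, registry).round(1).to_string())
print("worst levers:", rank_levers(deviation_table(matrix)).worst_first[:3])
```

prints

```
        food_security  right_to_food  poverty_inequality  environmental_performance  social_ecological_resilience  overall
system
B1                2.0            2.0                 2.0                        1.0                           3.0      2.0
B2                3.0            2.5                 1.5                        4.0                           3.0      2.8
B3                4.0            2.0                 3.0                        4.0                           4.0      3.4
K1                2.0            2.0                 3.0                        1.5                           3.0      2.3
K2                2.0            2.0                 2.0                        3.0                           3.0      2.4
K3                3.0            3.0                 3.0                        3.0                           3.0      3.0
worst levers: ('household_food_security', 'local_food_traditions', 'remedies_right_to_food')
```

The six columns are the five dimension medians and the overall score for
six synthetic food-system archetypes (`B1`/`K1` agro-industrial, `B2`
domestic–indigenous, `B3` agroecological, `K2` regional, `K3` local). The
agroecological and local archetypes score highest overall; the
agro-industrial ones are pulled down by environmental performance and right
to food while keeping medium-to-high resilience. The "worst levers" are the
indicators that most often fall below their system's reference median in
this draw.

The same pipeline is available from the shell:

```bash
foodsust simulate --seed 42 --out run      # write a synthetic score matrix
foodsust assess run/scores.csv --out run   # dimension medians + overall
foodsust deviations run/scores.csv --out run
foodsust pca run/scores.csv --cutoff 0.45 --out run
```

`assess`, `activities`, `deviations` and `pca` also accept a
supplementary-style `.xlsx` workbook of indicator ratings in place of the
CSV.

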