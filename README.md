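# candykano

Survey analytics for bipolar (forward/reverse) five-point Kano
questionnaires, implementing the **interval ("Candy") Kano model** alongside
its three classical comparators:

* **traditional method** — per-respondent evaluation-table classification
  plus the modal (frequency) rule;
* **Better–Worse method** — SI/DSI satisfaction coefficients with a
  quadrant cutoff;
* **ratio model** — per-item relative satisfaction/dissatisfaction shares
  β⁺/β⁻ classified against the grand mean θ = 1/n;
* **Candy model** — the same shares classified against the interval
  [θ − v·φ, θ + v·φ] (φ = range of all 2n shares, floating ratio v,
  default 1/6), which adds a fifth **Critical** category for items with
  above-interval sensitivity in both directions.

The package also covers the surrounding study workflow: response loading
and validity filtering, importance summaries and priority ordering,
importance–satisfaction correlation, questionnaire psychometrics
(Cronbach's α, KMO, Bartlett), demographic stratification with life-cycle
chain distances (I → A → O(C) → M), and a seedable synthetic-population
generator with plantable category archetypes.

A 46-item home-based elderly-care service study is packaged as fixtures
(`catalog_table5`, `profiles_table9`, `evaluation_matrix_table3`,
`differences_table13`) and used throughout the regression tests.

## Library quick start

```python
from candykano.survey_io import load_responses, filter_invalid, get_fixture
from candykano.candy_core import (
    SatisfactionProfile, aggregate, normalize, classify_all, count_categories,
)

# from raw responses (wide CSV: <code>_f, <code>_r, <code>_imp columns)
rs, summary = filter_invalid(load_responses("responses.csv"))
profile = normalize(aggregate(rs))

# or from the packaged printed profile
profile = SatisfactionProfile.from_table(get_fixture("profiles_table9"))

result = classify_all(profile, method="candy", params={"v": 1 / 6})
print(result.params)              # theta, phi, theta_low, theta_up
print(count_categories(result))   # e.g. {'C': 5, 'M': 7, 'O': 22, 'I': 7, 'A': 5}
```

## Command line

The console script `candykano` exposes subcommands `validate`, `classify`,
`compare-methods`, `importance`, `psychometrics`, `stratify`, `simulate`
and `report`:

```sh
# classify the packaged printed profile with the interval model
candykano classify --input fixture:table9 --method candy --out out/

# generate a synthetic study, then run the full report bundle
candykano simulate --q 370 --seed 1 --out responses.csv
candykano report --input responses.csv --group-by subgroup --out bundle/
```

`report` writes per-method classification CSVs, a side-by-side method
comparison, thresholds JSON, importance summaries, a psychometrics report,
stratified comparisons and a β⁻-vs-β⁺ scatter export. All outputs are
deterministic for a fixed input and seed.

## Layout

| module | contents |
|---|---|
| `candykano.survey_io` | data model, CSV I/O, validity filters, fixtures |
| `candykano.kano_traditional` | evaluation table, frequency method, Better–Worse |
| `candykano.candy_core` | coding, aggregation, normalization, thresholds, classifiers |
| `candykano.importance_stats` | category/service-group summaries, priority, correlation |
| `candykano.psychometrics` | Cronbach's α, KMO, Bartlett's sphericity |
| `candykano.stratified` | subgroup re-classification, chain distances, adjacency |
| `candykano.synthetic` | seedable generator with plantable archetypes |
| `candykano.cli` | command-line interface and report pipeline |

Notes on reproduction: recomputing the interval labels from the printed
4-decimal β values reproduces 45 of the 46 published labels; the single
discrepancy (item D2, printed A, recomputed O) is a rounding artifact —
its printed β⁺ = 0.0229 sits within 6e-6 of the upper bound 0.0229058.
The traditional and Better–Worse label columns of the printed study cannot
be re-derived from published data (they require the raw questionnaires)
and are shipped only as fixture columns.
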