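# dietopt

Diet optimization by linear programming: find the diet that minimizes
greenhouse-gas emissions (GHGE, kg CO2e/day) while meeting nutritional
reference bounds, staying within the observed consumption range of a
population, and respecting dietary-guideline policies.

The pipeline has five stages plus a synthetic-data generator:

| module | role |
| --- | --- |
| `dietopt.food_model` | food catalog (15 categories / 55 subcategories), nutrient compositions per 100 g, free/intrinsic sugar classification, exclusion filtering |
| `dietopt.ghge_db` | per-subcategory emission coefficients from literature data points: GWP conversion, indicator-product means, uncertainty-range rules (quartiles / min–max / ±50% / ±25%) |
| `dietopt.survey` | 3-day diary processing: per-subject daily intakes, sex-stratified mean/p5/p90 statistics, consumption-weighted nutrient content |
| `dietopt.constraints` | nutritional bounds (absolute and exact homogeneous percent-of-energy form), acceptability bounds (80–140% of mean total weight, p5–p90 boxes), healthy policy bounds (red meat 10–30 g/day, processed meat and alcohol zero, fruit & vegetables 400–500 g/day, pulses and fish ≥ 20 g/day) |
| `dietopt.optimizer` | HiGHS-backed LP solve, nutrient extremization, infeasibility diagnosis (remove a suspect bound, re-solve, report the achievable range), binding-constraint report |
| `dietopt.reporting` | observed-vs-optimized comparison tables, percent changes, per-category nutrient contribution shares |
| `dietopt.synthetic` | seeded scenario generator (`default_feasible`, `iron_scarce`, `red_meat_dominated`, `minimal_toy`) producing catalogs, GHGE data points and zero-inflated log-normal diaries with a planted feasible diet |

## Command-line usage

```sh
# generate a synthetic scenario (catalog.csv, ghge_points.csv, mapping.csv, diary.csv)
dietopt synth --scenario default_feasible --seed 1 --out data/

# build the per-subcategory GHGE coefficient table
dietopt build-ghge --points data/ghge_points.csv --mapping data/mapping.csv --out ghge.csv

# population statistics for one sex
dietopt stats --diary data/diary.csv --catalog data/catalog.csv --sex F --out stats/

# solve the GHGE-minimizing LP
dietopt optimize --sex F --stats stats/stats_F.csv --content stats/content_F.csv \
    --ghge ghge.csv --out results/

# or run everything end to end with comparison tables
dietopt report --diary data/diary.csv --catalog data/catalog.csv \
    --points data/ghge_points.csv --mapping data/mapping.csv --sex M --out report/
```

Default nutritional/policy bounds ship in
`src/dietopt/data/default_bounds.yaml`; pass `--bounds` to override.
The female iron band is excluded from the default set (it makes the
problem infeasible); enable it via
`build_problem(..., include_optional_nutrients=True)` to reproduce the
infeasibility diagnostic, e.g.:

```python
from dietopt import *

ds = generate_dataset(scenario("iron_scarce", seed=1))
catalog = filter_catalog(ds.catalog)
table = build_ghge_table(ds.points, ds.mapping)
stats = build_population_stats(ds.diary, catalog, "F")
problem = build_problem(stats, table, include_optional_nutrients=True)
report = diagnose_infeasibility(problem, ["iron"])   # achievable max < lb
```

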