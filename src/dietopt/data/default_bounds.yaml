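# Default nutritional bounds (per sex), healthy-policy targets and
# acceptability settings. Units: per_day bounds are kcal/day (energy),
# g/day (protein, fiber, alcohol), mg/day (cholesterol, calcium, iron,
# zinc) or ug/day (vitamin B12); percent_energy bounds are % of total
# dietary energy.
sexes:
  M:
    nutritional:
      energy: {lb: 2400, ub: 2460, unit: per_day}
      protein: {lb: 60, ub: 92, unit: per_day}
      total_fat: {lb: 24.5, ub: 30.8, unit: percent_energy}
      sfa: {lb: 7.0, ub: 10.1, unit: percent_energy}
      pufa: {lb: 4.8, ub: 10.1, unit: percent_energy}
      cholesterol: {lb: 250, ub: 300, unit: per_day}
      carbohydrate: {lb: 46.8, ub: 65.7, unit: percent_energy}
      total_sugar: {lb: 10.4, ub: 16.3, unit: percent_energy}
      free_sugar: {lb: 4.2, ub: 5.5, unit: percent_energy}
      fiber: {lb: 24, ub: 26, unit: per_day}
      calcium: {lb: 900, ub: 1100, unit: per_day}
      iron: {lb: 9, ub: 11, unit: per_day}
      zinc: {lb: 11, ub: 13, unit: per_day}
      vitamin_b12: {lb: 2, ub: 3, unit: per_day}
      alcohol: {lb: 0, ub: 0, unit: per_day}
  F:
    nutritional:
      energy: {lb: 1900, ub: 1982, unit: per_day}
      protein: {lb: 52, ub: 73, unit: per_day}
      total_fat: {lb: 24.1, ub: 31.3, unit: percent_energy}
      sfa: {lb: 6.4, ub: 10.4, unit: percent_energy}
      pufa: {lb: 4.5, ub: 10.4, unit: percent_energy}
      cholesterol: {lb: 250, ub: 300, unit: per_day}
      carbohydrate: {lb: 46.0, ub: 66.7, unit: percent_energy}
      total_sugar: {lb: 10.3, ub: 16.6, unit: percent_energy}
      free_sugar: {lb: 4.0, ub: 5.5, unit: percent_energy}
      fiber: {lb: 24, ub: 26, unit: per_day}
      calcium: {lb: 900, ub: 1100, unit: per_day}
      zinc: {lb: 8, ub: 10, unit: per_day}
      vitamin_b12: {lb: 2, ub: 3, unit: per_day}
      alcohol: {lb: 0, ub: 0, unit: per_day}
    # The female iron band is excluded from the default set (it renders
    # the problem infeasible); enable it explicitly to reproduce the
    # infeasibility diagnostic.
    optional_nutritional:
      iron: {lb: 17, ub: 19, unit: per_day}

policy:
  red_meat: {lb: 10, ub: 30}
  processed_meat: {lb: 0, ub: 0}
  alcoholic_beverages: {lb: 0, ub: 0}
  fruit_veg: {lb: 400, ub: 500}
  pulses: {lb: 20}
  fish: {lb: 20}

acceptability:
  weight_range: [0.8, 1.4]
  include_category_level: true

energy_factors: {fat: 9, protein: 4, carbohydrate: 4, alcohol: 7}
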