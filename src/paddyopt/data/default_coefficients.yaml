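# Default cost / GHG / energy coefficients for rice agricultural inputs.
# cost: CNY per unit, ghg: kg CO2-eq per unit, energy: MJ per unit.
# Units: fertilizers/seed/herbicide/pesticide per kg; labor and machinery per hour,
# EXCEPT labor cost which is per ha-season (the source table prices labor per ha).
# The seed and labor rows are typographically uncertain in the source table and are
# deliberately kept here, in one editable file, so they can be overridden.
items:
  n_rate:      {cost: 3.8,  ghg: 1.3,  energy: 60.6,  unit: kg}
  p_rate:      {cost: 1.25, ghg: 0.2,  energy: 11.93, unit: kg}
  k_rate:      {cost: 2.0,  ghg: 0.2,  energy: 6.7,   unit: kg}
  seed_rate:   {cost: 5.0,  ghg: 0.0,  energy: 17.0,  unit: kg}       # uncertain row
  herbicide:   {cost: 175.0, ghg: 6.30, energy: 238.0, unit: kg}
  pesticide:   {cost: 100.0, ghg: 5.10, energy: 199.0, unit: kg}
labor:                                                                 # uncertain rows
  MAT: {cost_per_season: 1500.0, ghg: 0.0, energy: 14.95, unit: h}
  MAD: {cost_per_season: 1500.0, ghg: 0.0, energy: 27.5,  unit: h}
machinery:
  MT: {cost: 120.0, ghg: 0.07, energy: 37.5,  unit: h}
  MD: {cost: 120.0, ghg: 0.07, energy: 34.95, unit: h}
outputs:
  grain_price: 2.7        # CNY/kg
  grain_energy: 14.7      # MJ/kg
  straw_energy: 12.5      # MJ/kg
# Straw yield is rarely reported; when missing it is imputed as straw = grain
# (harvest index 0.5) for energy-output purposes only.
straw_to_grain_ratio: 1.0
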