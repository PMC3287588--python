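# Mixotrophic growth: photons + CO2 + acetate.
condition: mixotrophic
fixed_growth_rate: 0.066   # h^-1
substrate_exchange: EX_photon_e
product_exchange: EX_h2_e
objective_1: [EX_photon_e, minimize uptake]
objective_2: [EX_h2_e, maximize]
bound_overrides:
  EX_photon_e: [-1000.0, 0.0]
  EX_co2_e: [-1000.0, 1000.0]
  EX_ac_e: [-1.5, 1000.0]
  EX_o2_e: [-1000.0, 1000.0]
  ATPM_c: [0.2, 1000.0]
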