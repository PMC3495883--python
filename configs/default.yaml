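composition_step: 25
equilibrium_tolerance: 0.02
inclusion_level: L1
last_k: 200
numeric_variables:
- stated_age
- partners_6mo
- reported_network_size
population:
  age_mode: 22
  age_range:
  - 18
  - 40
  degree_model: poisson
  degree_params:
    mean: 8.0
  n_individuals: 5000
  province_distribution:
    hanoi: 0.45
    hcmc: 0.37
    other: 0.18
  province_homophily: 0.7
  trait_specs:
  - categories:
    - men_only
    - other
    homophily: 0.3
    name: partner_preference
    probabilities:
    - 0.95
    - 0.05
  - categories:
    - for
    - against
    homophily: 0.1
    name: marriage_opinion
    probabilities:
    - 0.9
    - 0.1
  - categories:
    - daily
    - less_than_daily
    homophily: 0.1
    name: internet_use
    probabilities:
    - 0.8
    - 0.2
rng_seed: 0
simulation:
  coupons_per_participant: 4
  invalid_injection:
    duplicate_token_rate: 0.07
    fast_completion_rate: 0.02
    shared_ip_rate: 0.08
    underage_rate: 0.03
  max_waves: null
  n_seeds: 20
  network_size_fraction: 0.7
  network_size_missing_rate: 0.08
  participation_probability: 0.25
  rng_seed: 0
  seed_selection: uniform
  seed_trait: null
  with_replacement: false
variables: []
wave_threshold: 5
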