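# Default parameterisation of the ventral neural-tube patterning network
# (Pax6-Olig2-Nkx2.2 core).  Concentrations are in units of a typical
# "fully on" expression level divided by ~3 (so alpha/delta is the on-level);
# time in hours; the morphogen signal s is Gli activity in arbitrary units.
# Constants were calibrated so the wild-type system is a bistable pMN/p3
# switch with hysteresis and noise-driven pMN->p3 transitions occur on
# developmental timescales (<~50 h) in a narrow band of positions.
schema_version: 1
network:
  nodes: [Pax6, Olig2, Nkx2.2]
  interactions:
    - {source: Olig2,  target: Pax6,   sign: repression, K: 1.4, n: 2, weight: 0.7}
    - {source: Nkx2.2, target: Pax6,   sign: repression, K: 0.4, n: 4, weight: 1.0}
    - {source: Nkx2.2, target: Olig2,  sign: repression, K: 0.4, n: 4, weight: 1.0}
    - {source: Pax6,   target: Nkx2.2, sign: repression, K: 2.4, n: 4, weight: 1.0}
    - {source: Olig2,  target: Nkx2.2, sign: repression, K: 0.8, n: 3, weight: 1.0}
  signal_targets:
    - {node: Olig2,  effect: activation, K: 0.3, m: 2, weight: 0.9, basal: 0.1}
    - {node: Nkx2.2, effect: activation, K: 0.8, m: 2, weight: 1.0, basal: 0.0}
params:
  alpha: {Pax6: 3.0, Olig2: 3.0, Nkx2.2: 12.0}
  delta: {Pax6: 1.0, Olig2: 1.0, Nkx2.2: 1.0}
  omega: 220.0
signal_profile:
  s_max: 6.0
  lambda_frac: 0.15
  noise_sd: 0.0
mutants:
  pax6ko:
    deleted_nodes: [Pax6]
  o2e33:
    scalings:
      "signal_weight:Olig2": 0.85
      "basal_weight:Olig2": 0.85
      "edge_weight:Nkx2.2->Olig2": 0.9
simulation:
  dt: 0.02
  duration: 50.0
  n_positions: 40
  cells_per_position: 60
classification:
  other_band: 0.12
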