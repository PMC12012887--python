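# Layered autocatalytic controller, core demonstration run: the actuation
# gain k* steps from 1 to 50 at t = 15; output and free resource both
# return to their set-points Sigma = 1 and r* = 1.
circuit: layered_gene_expression
parameters:
  alpha2_star: 0.25
  gamma_c2: 0.25
  w1: 1.0
  w2: 1.0
  R_tot: 100.0
initial_state: {x1: 0.0, z1: 0.1, z2: 50.0}
horizon: 60.0
events:
  - {time: 15.0, parameter: k_star, action: set, value: 50.0}
scan: {axis1: alpha2_star, axis2: gamma_c2, grid1: [0.05, 1.0, 12], grid2: [0.05, 1.0, 12]}
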