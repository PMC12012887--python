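# Embedded gene-expression control under external resource loads: the
# aggregate zeroth-order load Q0 steps 10-fold at t = 15 and is rejected.
circuit: embedded_gene_expression
parameters:
  alpha2_star: 0.25
  gamma_c2: 0.25
  Q0: 1.0e-3
initial_state: {x1: 0.0, z1: 0.1, z2: 50.0}
horizon: 60.0
events:
  - {time: 15.0, parameter: Q0, action: scale, value: 10.0}
scan: {axis1: R_tot, axis2: k_star, grid1: [5.0, 200.0, 12], grid2: [0.5, 20.0, 12], contour: x1}
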