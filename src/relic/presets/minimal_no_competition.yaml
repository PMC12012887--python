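# Minimal autocatalytic loop, resource-unlimited regime: all competition
# gains zero, so a 20% actuation step at t = 15 is perfectly rejected.
circuit: minimal_gene_expression
parameters:
  w_z1: 0.0
  w_bar_lin: 0.0
  w_bar_quad: 0.0
initial_state: {x1: 0.0, z1: 0.1}
horizon: 60.0
events:
  - {time: 15.0, parameter: k_star, action: scale, value: 1.2}
notes: {expect: "output returns to its pre-step steady state (RPA)"}
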