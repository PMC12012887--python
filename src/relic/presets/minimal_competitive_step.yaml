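# Minimal autocatalytic loop competing for a shared pool: the same 20%
# actuation step now leaves a residual steady-state error (e_p != 1).
circuit: minimal_gene_expression
initial_state: {x1: 0.0, z1: 0.1}
horizon: 300.0
events:
  - {time: 150.0, parameter: k_star, action: scale, value: 1.2}
notes: {expect: "imperfect adaptation; deviation shrinks with R_tot and with the gains"}
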