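# Single-pool ratiometric controller with linear response maps;
# commanded ratio Gamma = 2.
circuit: ratiometric_gene_expression
initial_state: {x1: 0.1, x2: 0.1, z1: 0.1, z2: 1.0}
horizon: 400.0
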