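# Operon gene-ratio circuit with separate transcriptional (R1) and
# translational (R2) pools; commanded ratio Gamma = 2.
circuit: operon_ratio
initial_state: {m_p: 0.1, m_a: 0.0, x1: 0.1, x2: 0.1, z1: 0.1, z2: 1.0}
horizon: 400.0
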