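# Two-strain consortium integrator around a single-species process
# (x1 produced by N1's growth); time in hours.
circuit: consortium
initial_state: {N1: 10.0, N2: 10.0, x1: 0.0}
horizon: 300.0
scan: {axis1: theta1, axis2: gamma, grid1: [0.02, 0.3, 10], grid2: [0.05, 0.5, 10], contour: x1}
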