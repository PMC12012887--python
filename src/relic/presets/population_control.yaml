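# Three-strain population control: N1/N2 regulate the density of N3
# through the AHL channels A1 (actuation) and A3 (sensing); hours.
circuit: population_control
initial_state: {N1: 10.0, N2: 10.0, N3: 10.0, a1: 0.0, a3: 0.0}
horizon: 600.0
scan: {axis1: rho3, axis2: gamma, grid1: [0.2, 1.0, 10], grid2: [0.05, 0.3, 10], contour: a3}
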