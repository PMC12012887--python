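# Four-strain coculture composition control; the sensing gain rho4 is
# calibrated so the commanded ratio N3/N4 is 2, then scaled 4-fold at
# t = 600 h, stepping the commanded ratio to 4.
circuit: coculture_ratio
parameters:
  rho4: 2.0
initial_state: {N1: 50.0, N2: 50.0, N3: 100.0, N4: 50.0, a1: 0.0, a2: 0.0, a3: 0.0, a4: 0.0}
horizon: 1200.0
events:
  - {time: 600.0, parameter: rho4, action: scale, value: 4.0}
scan: {axis1: rho2, axis2: gamma, grid1: [0.5, 4.0, 10], grid2: [0.02, 0.2, 10]}
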