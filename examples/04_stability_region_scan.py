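"""Local stability region of the embedded control loop.

Sweeps total resource capacity against actuation gain, classifying each
cell by positive-equilibrium existence and Jacobian spectrum, and prints
an ASCII map.  The infeasible band at low capacity follows the analytic
boundary R_tot = r* + w1 gamma_p1 Sigma / k*.
"""

import numpy as np

from relic.intracellular import layered_gene_expression_circuit
from relic.motifs import LayeredMotifParams, layered_setpoint
from relic.stability import stability_region_scan

m = layered_gene_expression_circuit()
p = m.params
sp = layered_setpoint(LayeredMotifParams(
    p["alpha1_star"], p["alpha2_star"], p["gamma_c2"],
    p["sense_gain"], p["k_star"], p["w1"], p["w2"]))

R_grid = np.linspace(0.5, 8.0, 10)
k_grid = np.linspace(0.25, 4.0, 10)
amap = stability_region_scan(m, "R_tot", "k_star", R_grid, k_grid,
                             {"x1": 0.5, "z1": 0.5, "z2": 5.0}, contour="x1")

print("rows: R_tot (down = small), cols: k_star; '#' stable, '.' not")
for i in range(len(R_grid) - 1, -1, -1):
    row = "".join("#" if amap.verdicts[i, j] else "." for j in range(len(k_grid)))
    boundary = sp.r_star + p["w1"] * p["gamma_p1"] * sp.sigma / k_grid[0]
    print(f"  R_tot={R_grid[i]:5.2f}  {row}")
print(f"\nanalytic feasibility boundary at k* = {k_grid[0]:.2f}: "
      f"R_tot = {sp.r_star + p['w1'] * p['gamma_p1'] * sp.sigma / k_grid[0]:.2f}")
print(f"stable cells: {int(amap.verdicts.sum())}/{amap.verdicts.size}; "
      f"regulated output on stable cells = {np.nanmean(np.where(amap.verdicts, amap.contours, np.nan)):.4f}"
      f" (set-point Sigma = {sp.sigma})")
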