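"""Brushing-speed x brushing-depth study at desk scale.

Reproduces the two study slices — depth in {r, r/2, r/4} at V = 0.1 m/s and
speed in {0.05, 0.10, 0.15} m/s at d_z = r — with a shortened stroke so the
five runs finish in a few minutes, and prints the cross-run wear table.
"""

from brushwear import SimulationConfig, run_sweep

base = SimulationConfig(stroke=14e-3)  # quarter stroke: ~minutes, not tens
results, table = run_sweep(base, progress=False)
print(table.to_string(index=False))
print(
    "\nEach row is one (V, d_z) condition: total Archard wear volume (per\n"
    "unit K), the share and per-area density of wear in the groove band,\n"
    "the top-bottom symmetry score, and the per-tip force aggregates.\n"
    "Compare total_wear down each slice to see how brushing depth (force)\n"
    "and brushing speed shift tooth abrasion."
)
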