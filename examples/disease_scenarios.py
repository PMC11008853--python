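"""Survey the calibrated scenario registry.

Simulates every shipped experimental condition noise-free and prints the
endpoint cumulative mass, the published QC window where one exists, and
the disease-vs-control fold changes the calibration encodes.
"""

from dermakin import scenario_defaults

print(f"{'scenario':>22} {'grid':>10} {'endpoint':>10} {'unit':>8}  QC window")
for sc in scenario_defaults():
    grid = f"{sc.interval_min}min/{sc.duration_h:g}h"
    win = "-" if sc.qc_window is None else f"[{sc.qc_window[0]:g}, {sc.qc_window[1]:g}]"
    print(f"{sc.id:>22} {grid:>10} {sc.noise_free_endpoint:10.1f} {sc.unit:>8}  {win}")

ep = {s.id: s.noise_free_endpoint for s in scenario_defaults()}
print("\nDisease-vs-control calibration anchors:")
print(f"  psoriatic / control at 24 h : {ep['psoriasis-imq-24h'] / ep['psoriasis-control-24h']:.2f}x")
print(f"  psoriatic / control at 96 h : {ep['psoriasis-imq-96h'] / ep['psoriasis-control-96h']:.2f}x")
print(f"  allergic ear vs control     : +{100 * (ep['acd-tncb'] / ep['acd-control'] - 1):.0f}%")
print(f"  32 C vs ambient caffeine    : {ep['caffeine-32c-6h'] / ep['caffeine-rt-6h']:.2f}x")
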