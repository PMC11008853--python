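"""Slow and rapid phases of a cumulative penetration curve.

The anti-inflammatory creams release drug slowly at first (formulation
release) and faster later (absorption through the hydrated skin).  The
two-segment continuous regression quantifies that visual impression with
a breakpoint and two slopes.
"""

from dermakin import get_scenario, two_phase_regression

scenario = get_scenario("piroxicam-6h")
curve = scenario.simulate()
fit = two_phase_regression(curve)

print(f"scenario: {scenario.id} ({scenario.description})")
print(f"breakpoint      : {fit.breakpoint:.1f} h")
print(f"slow-phase slope: {fit.slope_slow:8.1f} {scenario.unit}/h")
print(f"rapid slope     : {fit.slope_rapid:8.1f} {scenario.unit}/h")
print(f"residual SS     : {fit.rss:.3g}")
print("\nThe rapid phase is steeper than the slow phase: the lag while the")
print("drug loads the upper skin compartments, then near-linear delivery.")
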