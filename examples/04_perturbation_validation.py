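"""Validating TIDES with a simulated acute inhibition.

If TIDES reports when the edge X -> Z is strong, inhibiting X should
depress Z most at exactly those pseudotimes.  The generator produces a
control/perturbed pair whose true inhibition effect scales with the
generative coupling g(t); the impact curve (control trend minus
perturbed trend of Z) is then aligned with the TIDES curve by
cross-correlation.
"""

from tides import impact_curve, match_curves, smooth_curve, tides_curve
from tides.simulate import (EdgeModulationSpec, PanelSpec, simulate_perturbation,
                            unimodal_coupling)
from tides.trajectory import marker_trend

mod = EdgeModulationSpec(coupling=unimodal_coupling(peak=0.5, width=0.15, height=1.5))
spec = PanelSpec(n_cells=5000,
                 markers={"E-cadherin": "decreasing", "Vimentin": "increasing",
                          "X": "flat", "Z": "flat"},
                 couplings={("X", "Z"): mod}, seed=0)
control, perturbed = simulate_perturbation(spec, ("X", "Z"), effect_scale=0.8)

curve = smooth_curve(tides_curve(control, "X", "Z"))
impact = impact_curve(marker_trend(control, "Z"), marker_trend(perturbed, "Z"))
result = match_curves(curve, impact)

print(f"TIDES vs impact: best lag {result.lag_time:+.3f} pseudotime units "
      f"({result.lag_bins:+d} bins), Pearson r = {result.r:.3f}")
# r close to 1 means the inhibition hurt the target exactly where TIDES
# said the edge was active - the curve validates the inferred dynamics.
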