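"""Phenotype gating and a config-driven end-to-end run.

Gates an EMT-like panel into epithelial / transitional / mesenchymal
classes with the standard E-cadherin / Vimentin thresholds, then runs
the whole pipeline (simulate -> TIDES -> scores) from a dict config.
"""

from tides import GateSpec, gate_fractions, run_pipeline
from tides.simulate import PanelSpec, simulate_emt_panel

cells, _ = simulate_emt_panel(PanelSpec(n_cells=5000, seed=0))
fractions = gate_fractions(cells, GateSpec())
print("gate fractions (Vimentin < 2 epithelial; "
      "E-cadherin < 2.5 & Vimentin > 4 mesenchymal):")
print(fractions.to_string(float_format=lambda v: f"{v:.3f}"))

manifest = run_pipeline({
    "seed": 0, "bins": 64, "epsilon": 0.9,
    "simulate": {"n_cells": 2000, "markers": {"X": "flat", "Z": "flat"}},
    "edges": [["X", "Z"]],
    "output_dir": "pipeline_output",
})
print("\npipeline artifacts:")
for path in manifest["outputs"]:
    print(" ", path)
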