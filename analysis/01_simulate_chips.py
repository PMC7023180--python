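#!/usr/bin/env python
"""Simulate the full sensing campaign: 8 medical chemicals (4 estrogens,
4 antibiotics) x 4 temperatures, one pre/post chip-image pair each.

Writes the dataset (PNGs, manifest, ground truth) to results/dataset/.
"""

from pathlib import Path

from phagesensor import default_scenario, generate_dataset

OUT = Path(__file__).resolve().parent.parent / "results" / "dataset"

scenario = default_scenario(seed=20240601)
manifest = generate_dataset(scenario, OUT)

print(f"wrote {len(manifest)} pre/post image pairs to {OUT}")
print(f"analytes: {', '.join(scenario.analyte_ids)}")
print(f"temperatures (C): {', '.join(str(int(t)) for t in scenario.temperatures_c)}")
print(f"pixel noise sd: {scenario.noise_sd} counts")
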