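"""Simulate a virtual study area, species and occurrence sample.

Builds a 72x72 km landscape at 1-km resolution with 45 named predictor
layers, defines a narrow-range virtual species with one increasing, one
decreasing and one unimodal response, and draws presence records in
proportion to its true suitability.
"""

import numpy as np

import sdmrisk as s

spec = s.LandscapeSpec(n_rows=72, n_cols=72, n_layers=45, seed=42,
                       mask_fraction=0.05)
stack = s.generate_env_stack(spec)
truth = s.default_truth_model(stack)
suit = s.truth_suitability(stack, truth)
occ = s.sample_occurrences(suit, n_presence=200, seed=43)

print(f"stack: {stack.n_layers} layers on {stack.shape[0]}x{stack.shape[1]} "
      f"km grid, {int(stack.mask.sum())} valid cells")
print(f"species drivers: {truth.layer_names}")
vals = suit.values[stack.mask]
print(f"true suitability: mean {vals.mean():.3f}, "
      f"fraction above 0.5 = {(vals > 0.5).mean():.3f}")
print(f"{len(occ)} presence records; mean suitability at presences "
      f"{np.nanmean(suit.sample(occ.points)):.3f}")
# A narrow-range species occupies a small, highly suitable fraction of the
# landscape; presences concentrate where suitability is high.
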