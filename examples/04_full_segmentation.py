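"""End-to-end segmentation of a phantom and evaluation against truth.

Runs the whole chain — denoising, multiscale enhancement, mixture fit,
fraction threshold, sigmoid transform, initial labeling, MRF/ICM
refinement — and scores the result.  DSC is the overlap headline; the MRF
step removes speckle false positives, which is visible as the jump from
the initial to the refined Dice value.
"""

import numpy as np

from cerevess.phantom import demo_spec, make_phantom
from cerevess.pipeline import PipelineConfig, evaluate_against_truth, segment

volume, truth = make_phantom(demo_spec(shape=(64, 64, 64), seed=7))
result = segment(volume, PipelineConfig(mask_source="none"))

rep = result.report
print("stages:", " -> ".join(rep["stages"]))
print(f"W = {rep['W']:.4f}, Q = {rep['Q']:.4f}, "
      f"ICM sweeps = {rep['sweeps_run']}")

initial = ((result.transformed >= 0.5) & result.mask).astype(np.uint8)
before = evaluate_against_truth(initial, truth)
after = evaluate_against_truth(result.labels, truth)
for name, ev in (("initial labels", before), ("after MRF", after)):
    print(f"{name:15s} DSC={ev['DSC']:.3f} Sen={ev['Sen']:.3f} "
          f"PPV={ev['PPV']:.3f} Acc={ev['Acc']:.3f}")
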