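"""SVD clutter rejection: strong static tissue vs flowing bubbles.

Renders the same bubbles with and without a static clutter field 30 dB
above the bubble echoes, filters the cluttered series, and reports how
much clutter energy one removed eigenvector eliminates.
"""

import numpy as np

from ulm3d.evaluation import clutter_suppression_experiment

out = clutter_suppression_experiment(seed=0, n_frames=150, clutter_db=30.0)
print(f"clutter energy suppression: {out['suppression_db']:.1f} dB "
      f"(one singular component removed from a 150-frame sub-block)")
print(f"worst bubble peak displacement vs bubble-only render: "
      f"{out['max_peak_offset_vox']} voxel(s)")
print("The static field is rank 1 in the Casorati sense, so a single "
      "removed component captures essentially all of it while the moving "
      "bubbles survive.")
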