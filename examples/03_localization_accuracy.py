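"""Sub-voxel localization precision versus image SNR.

Renders isolated bubbles at known sub-voxel positions, adds complex
white noise, runs the detection + paraboloid-fit chain, and prints the
median 3D error — ULM's super-resolution claim in one number.
"""

from ulm3d.evaluation import localization_error_experiment

for snr_db in (30.0, 20.0):
    out = localization_error_experiment(n_bubbles=200, snr_db=snr_db, seed=3)
    print(f"SNR {snr_db:.0f} dB: {out['n_localized']}/{out['n_bubbles']} bubbles "
          f"localized, median error {out['median_error_um']:.1f} um, "
          f"90th percentile {out['p90_error_um']:.1f} um")
print("Voxels are 100 x 100 x 40 um: localization is 1-2 orders of "
      "magnitude finer than the grid.")
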