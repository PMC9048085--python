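"""Flow-radius scaling across a vascular tree (generalized Murray law).

Processes a branching phantom end to end — bubble transport, maps,
skeletonization, per-segment Poiseuille flow — and fits the power law
Q ~ R^gamma, whose exponent characterizes vascular scaling.
"""

from ulm3d.evaluation import tree_exponent_experiment

out = tree_exponent_experiment(seed=9, gamma=3.0, depth=3)
print(f"{out['n_tracks']} tracks; {out['n_segments_used']} vessel segments in the fit")
print(f"recovered exponent {out['exponent']:.2f} (truth gamma = "
      f"{out['gamma_true']}), log-log r^2 = {out['r_squared']:.3f}")
print("Flow was never measured directly: it comes from skeleton radii and "
      "centreline velocities, exactly as on in vivo maps.")
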