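"""Generate a labeled synthetic tracking study and look at its composition.

Builds the heterogeneous three-medium design (mixtures of immobile,
subdiffusive and diffusive populations with medium-specific weights,
100-frame trajectories at 1 Hz, 20 nm localization noise) and prints the
per-medium trajectory counts and motion-model composition.
"""

from diffprint.simulate import build_synthetic_study, default_study_design

design = default_study_design("heterogeneous", n_per_cell=50)
trajectories, labels = build_synthetic_study(design, seed=0)

print(f"{len(trajectories)} trajectories of {len(trajectories[0])} frames "
      f"(dt = {trajectories[0].dt} s)\n")
print("composition (fraction of trajectories per motion model):")
comp = (labels.groupby("medium")["model"].value_counts(normalize=True)
        .unstack(fill_value=0.0).round(2))
print(comp)
print("\nEach row is one medium; immobile/fbm weights differ between media, "
      "which is the class signal the downstream classifiers learn.")
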