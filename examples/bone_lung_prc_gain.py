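"""Material dependence of positron-range correction: lung vs. bone.

Simulates the bone-lung phantom (three cold 50 mm cylinders at -800, +500
and +1000 HU, each with hot 8.5/19.4 mm spheres) and compares OSEM with and
without full PRC at matched background noise.  The correction should buy far
more contrast inside the lung cylinder, where the ^124I positron cloud is
widest, than inside bone.
"""

from prcrecon.experiment import ExperimentConfig, run_experiment

config = ExperimentConfig.bone_lung(
    seed=0,
    variants={"OSEM": 6, "OSEM+PRC": 10},
    kernel_events=50_000,
)
study = run_experiment(config)

cr = study.matched_cr
print(cr.round(3).to_string())
print("\nrelative CR gain from full PRC (19.4 mm spheres):")
for label in ("lung_19.4mm", "bone+500HU_19.4mm", "bone+1000HU_19.4mm"):
    gain = 100.0 * (cr.loc["OSEM+PRC", label] - cr.loc["OSEM", label]) / cr.loc["OSEM", label]
    print(f"  {label:20s} {gain:+6.1f}%")
print(
    "\nThe lung cylinder benefits most: its range kernel is ~4x wider than\n"
    "water's, so uncorrected reconstruction loses far more contrast there."
)
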