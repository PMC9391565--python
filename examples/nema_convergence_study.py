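"""Contrast recovery vs. noise for PRC reconstruction variants.

Runs a reduced image-quality phantom study (small grid, three hot spheres,
three variants) and prints the per-iteration contrast recovery of the
smallest sphere against background noise, plus the matched-noise comparison.
The full-size study (160x160x24, six spheres, all six variants) is what
scripts/acceptance.py reproduces; this example keeps the run under a minute.
"""

from prcrecon.experiment import ExperimentConfig, run_experiment

config = ExperimentConfig.nema_iq(
    seed=0,
    shape=(96, 96, 16),
    n_angles=48,
    n_subsets=12,
    total_counts=4e7,
    kernel_events=50_000,
    variants={"OSEM": 4, "OSEM+PRC simplified": 4, "OSEM+PRC": 8},
    phantom_kwargs=dict(
        body_diameter=170.0,
        ring_radius=40.0,
        sphere_diameters=(10.0, 17.0, 28.0),
        n_background_vois=6,
        background_voi_diameter=20.0,
        edge_margin=8.0,
    ),
)
study = run_experiment(config)

tab = study.evaluation.per_iteration
print("per-iteration noise (%) and CR of the 10 mm sphere:")
for variant in config.variants:
    sub = tab[(tab.variant == variant) & (tab.voi_label == "10mm")].sort_values("iteration")
    pairs = ", ".join(
        f"it{int(r.iteration)}: {r.noise_pct:4.1f}% / {r.contrast_recovery:.2f}"
        for r in sub.itertuples()
    )
    print(f"  {variant:22s} {pairs}")

print("\nmatched at ~10% background noise:")
print(study.matched_cr.round(3).to_string())
print(
    "\nThe simplified scheme tracks plain OSEM's fast noise growth (its\n"
    "back-projector ignores the range blur), while the full scheme buys its\n"
    "higher small-sphere contrast with slower, better-conditioned updates."
)
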