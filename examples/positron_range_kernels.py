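"""Monte-Carlo positron-range kernels for ^124I in lung, water and bone.

Builds the uniform kernel bank at 1e5 annihilation events per material and
prints the transaxial kernel width per material.  The widths order inversely
with mass density — the whole reason positron-range correction matters most
in lung — and the lung kernel loses a sizeable fraction of events beyond the
11-voxel support (recorded as the discarded fraction).
"""

import numpy as np

from prcrecon import I124, build_kernel_bank, sample_annihilation_displacement

bank = build_kernel_bank(n_events=100_000, seed=0)

print("material   density   FWHM      central   discarded")
for mat in bank.materials:
    k = bank.kernels[mat.name]
    print(
        f"{mat.name:8s} {mat.mass_density:6.2f}    {k.fwhm():4.2f} mm   "
        f"{k.values[5, 5, 5]:6.3f}    {k.discarded_fraction:5.1%}"
    )

disp = sample_annihilation_displacement(I124, 1.0, np.random.default_rng(0), 50_000)
r = np.linalg.norm(disp, axis=1)
print(
    f"\nwater displacement: mean {r.mean():.2f} mm, "
    f"95th pct {np.quantile(r, 0.95):.2f} mm, max {r.max():.2f} mm"
)
print(
    "The FWHM ordering lung > water > bone and the ~1/density scaling are\n"
    "what the spatially variant correction kernels inherit per voxel."
)
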