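# prcrecon

Positron-range-corrected OSEM PET reconstruction at desk scale.

High-energy β⁺ emitters such as ¹²⁴I blur PET images badly: the positron
travels millimetres (≈2.7 mm on average in water, ~4× further in lung)
before annihilating, and that range blur sits on top of the detector's own
resolution.  `prcrecon` is a research toolbox for studying how to correct
this *inside* iterative reconstruction, for medical-physics and
reconstruction researchers who want a transparent, fully testable sandbox
rather than a vendor black box.

The system matrix is factorized as **A = W·X·H** — per-LOR attenuation and
normalization weights `W`, exact sparse line-integral projector `X`, and an
image-space resolution factor `H` holding a spatially variant,
tissue-dependent positron-range (PR) kernel and optionally a Gaussian
detector PSF.  The ordered-subsets EM update

    f_j ← f_j / (Σ_{i∈S} a_ij) · Σ_{i∈S} a_ij · m_i / (Σ_k a_ik f_k)

is provided in six variants: plain **OSEM**, **PSF** (detector blur in `H`),
and each combined with PR correction in *simplified* form (PR blur applied
to the image estimate before forward projection only — the back-projector
and the sensitivity image stay those of plain OSEM/PSF) or *full* form (PR
blur and its exact adjoint in forward projection, back projection and the
sensitivity image).

Around the reconstruction sit the pieces needed for a self-contained study:

* **Monte-Carlo PR kernels** — ¹²⁴I β⁺ branches with the Coulomb-corrected
  allowed spectrum, an empirical range–energy relation scaled by 1/density;
  uniform 11×11×11 kernels for lung / soft tissue / bone, composed per
  voxel from a CT-derived material map (air counts as lung);
* **digital phantoms** — image-quality (six spheres 10–37 mm, 30/6 kBq/ml),
  small-tumor (3.7–9.7 mm, 25/1.2 kBq/ml) and bone–lung (cold −800/+500/
  +1000 HU cylinders with hot 8.5/19.4 mm spheres), with their VOI sets;
* **acquisition simulator** — parallel-beam multi-slice sinograms with
  attenuation and Poisson noise;
* **evaluation protocol** — contrast recovery `(S̄/B̄)/ratio`, background
  noise `100·SD/mean` over pooled background VOIs, matched-noise iteration
  selection, and Gibbs edge-overshoot profiling.

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

`examples/nema_convergence_study.py` runs a reduced image-quality study
(96×96×16 grid, three spheres, three variants, ~1 minute) and prints:

```
per-iteration noise (%) and CR of the 10 mm sphere:
  OSEM                   it1:  6.7% / 0.42, it2: 10.3% / 0.51, it3: 13.1% / 0.54, it4: 15.2% / 0.55
  OSEM+PRC simplified    it1:  6.7% / 0.43, it2: 11.9% / 0.56, it3: 16.9% / 0.62, it4: 21.6% / 0.65
  OSEM+PRC               it1:  3.4% / 0.38, it2:  4.0% / 0.51, ... it7:  9.7% / 0.65, it8: 10.7% / 0.66

matched at ~10% background noise:
                     iteration  noise_pct   10mm   17mm   28mm
OSEM                         2     10.257  0.511  0.690  0.811
OSEM+PRC simplified          2     11.860  0.564  0.737  0.844
OSEM+PRC                     7      9.676  0.651  0.763  0.858
```

Read it row-wise: each iteration trades noise for contrast.  The simplified
correction inherits plain OSEM's fast noise growth (its forward and
backward projectors disagree), reaching 10 % noise after only 2 iterations;
the full correction converges more slowly but, compared at the *same* 10 %
noise level, recovers clearly more contrast in the smallest sphere
(0.65 vs 0.51).  That matched-noise ordering — full > simplified > none,
with the gap largest for small spheres and in lung — is the package's
central reproducible result.

Other examples: `examples/positron_range_kernels.py` (kernel widths per
material), `examples/bone_lung_prc_gain.py` (material dependence of the
correction).  A thin CLI mirrors the pipeline stages:

```bash
prcrecon kernels --events 200000 --seed 1 --out bank.h5
prcrecon phantom --name nema_iq --grid 160,160,24 --out phantom/
prcrecon simulate --phantom-dir phantom/ --bank bank.h5 --counts 1.2e8 --out sino.h5
prcrecon reconstruct --sino sino.h5 --phantom-dir phantom/ --bank bank.h5 --variant "PSF+PRC" --out recon.nii
prcrecon evaluate --image recon.nii --vois phantom/vois.json --ratio 5
prcrecon run --phantom nema_iq --seed 1 --out study/      # end-to-end
```

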