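"""End-to-end phantom studies: kernels -> phantom -> acquisition ->
reconstruction variants -> contrast/noise evaluation.

A study is fully described by an :class:`ExperimentConfig`; given the same
config and seed, a run is deterministic down to the metric tables.  The
scaled-down defaults (grid, counts, angles) are the package's working sizes
for desk-scale experiments; see docs/methods.md for how they were chosen.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .kernels import DEFAULT_MATERIALS, I124, KernelBank, build_kernel_bank
from .metrics import (
    EvaluationResult,
    convergence_table,
    edge_overshoot,
    match_all_variants,
    matched_cr_table,
)
from .phantoms import PhantomSet, hu_to_mu, make_bone_lung, make_nema_iq, make_small_tumor, segment_materials
from .projector import (
    PRModel,
    ProjectionData,
    ScannerGeometry,
    SystemModel,
    attenuation_factors,
    simulate_acquisition,
)
from .recon import VARIANTS, ReconResult, run_variant_suite

log = logging.getLogger("prcrecon")

PHANTOM_BUILDERS = {
    "nema_iq": make_nema_iq,
    "small_tumor": make_small_tumor,
    "bone_lung": make_bone_lung,
}


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one phantom study."""

    phantom: str = "nema_iq"
    shape: tuple[int, int, int] = (160, 160, 24)
    voxel_size: float = 2.0
    n_angles: int = 120
    n_subsets: int = 12
    total_counts: float = 1.2e8  # calibrated: ~10% background noise at OSEM iteration 2
    seed: int = 0
    detector_fwhm: float = 4.4  # mm, both in simulation and PSF reconstruction
    simulate_pr: bool = True  # positron-range blur in the ground-truth forward model
    kernel_size: tuple[int, int, int] = (11, 11, 11)
    kernel_events: int = 200_000
    variants: dict[str, int] = field(
        default_factory=lambda: {name: VARIANTS[name][2] for name in VARIANTS}
    )
    target_noise_pct: float = 10.0
    phantom_kwargs: dict = field(default_factory=dict)  # geometry overrides

    def __post_init__(self) -> None:
        if self.phantom not in PHANTOM_BUILDERS:
            raise ValueError(
                f"unknown phantom {self.phantom!r}; choose from {list(PHANTOM_BUILDERS)}"
            )
        for name in self.variants:
            if name not in VARIANTS:
                raise ValueError(f"unknown variant {name!r}")

    @classmethod
    def nema_iq(cls, **overrides) -> "ExperimentConfig":
        return cls(phantom="nema_iq", **overrides)

    @classmethod
    def small_tumor(cls, **overrides) -> "ExperimentConfig":
        overrides.setdefault("target_noise_pct", 33.0)
        overrides.setdefault("total_counts", 1.2e7)
        return cls(phantom="small_tumor", **overrides)

    @classmethod
    def bone_lung(cls, **overrides) -> "ExperimentConfig":
        overrides.setdefault("shape", (128, 128, 24))
        overrides.setdefault("total_counts", 1.0e8)
        return cls(phantom="bone_lung", **overrides)

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        d["shape"] = list(self.shape)
        d["kernel_size"] = list(self.kernel_size)
        return d


@dataclass
class ExperimentArtifacts:
    """In-memory products of one study."""

    config: ExperimentConfig
    phantom: PhantomSet
    bank: KernelBank
    sinogram: ProjectionData
    model: SystemModel
    results: dict[str, ReconResult]
    evaluation: EvaluationResult
    matched_cr: pd.DataFrame
    manifest: dict


def _derived_seeds(seed: int, n: int) -> list[int]:
    return [int(s % (2**31)) for s in np.random.SeedSequence(seed).generate_state(n)]


def run_experiment(
    config: ExperimentConfig,
    out_dir: str | Path | None = None,
    dry_run: bool = False,
) -> ExperimentArtifacts | dict:
    """Run one phantom study end to end.

    With ``out_dir`` set, volumes (NIfTI), the sinogram (HDF5), the metric
    tables (CSV) and a manifest (JSON, config + seeds + version) are written.
    ``dry_run`` validates the plan and returns the manifest without
    computing.
    """
    kernel_seed, acq_seed = _derived_seeds(config.seed, 2)
    manifest = {
        "config": config.to_json(),
        "derived_seeds": {"kernels": kernel_seed, "acquisition": acq_seed},
        "prcrecon_version": __version__,
    }
    if dry_run:
        log.info("dry run: validated config for %s", config.phantom)
        return manifest

    stages: dict[str, float] = {}
    t0 = time.time()

    phantom = PHANTOM_BUILDERS[config.phantom](
        config.shape, config.voxel_size, **config.phantom_kwargs
    )
    stages["phantom"] = time.time() - t0

    t = time.time()
    bank = build_kernel_bank(
        I124,
        DEFAULT_MATERIALS,
        (config.voxel_size,) * 3,
        config.kernel_size,
        config.kernel_events,
        kernel_seed,
    )
    stages["kernels"] = time.time() - t

    t = time.time()
    geometry = ScannerGeometry(
        n_angles=config.n_angles,
        n_radial=config.shape[0],
        radial_spacing=config.voxel_size,
        n_planes=config.shape[2],
    )
    mu = hu_to_mu(phantom.hu)
    material_map = segment_materials(phantom.hu)
    model = SystemModel(
        geometry=geometry,
        attenuation=attenuation_factors(mu, geometry),
        detector_fwhm=config.detector_fwhm,
        pr=PRModel(bank, material_map) if config.simulate_pr else None,
    )
    sinogram = simulate_acquisition(
        phantom, model, config.total_counts, seed=acq_seed, noiseless=False
    )
    stages["simulate"] = time.time() - t

    t = time.time()
    results = run_variant_suite(
        sinogram,
        model,
        variants=list(config.variants),
        n_iterations=config.variants,
        n_subsets=config.n_subsets,
        keep_iterates=True,
    )
    stages["reconstruct"] = time.time() - t

    t = time.time()
    evaluation = convergence_table(results, phantom.vois, phantom.activity_ratio)
    matched = match_all_variants(evaluation, config.target_noise_pct)
    matched_cr = matched_cr_table(evaluation, config.target_noise_pct)
    stages["evaluate"] = time.time() - t

    manifest["stage_seconds"] = {k: round(v, 2) for k, v in stages.items()}
    manifest["matched_iterations"] = {
        v: {"iteration": m.iteration, "noise_pct": m.noise_pct, "reachable": m.reachable}
        for v, m in matched.items()
    }
    for stage, dt in stages.items():
        log.info("stage %-12s %.1fs", stage, dt)

    artifacts = ExperimentArtifacts(
        config, phantom, bank, sinogram, model, results, evaluation, matched_cr, manifest
    )
    if out_dir is not None:
        _write_artifacts(artifacts, Path(out_dir))
    return artifacts


def _write_artifacts(artifacts: ExperimentArtifacts, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts.phantom.save(out_dir / "phantom")
    artifacts.bank.save_hdf5(out_dir / "kernel_bank.h5")
    artifacts.sinogram.save_hdf5(out_dir / "sinogram.h5")
    recon_dir = out_dir / "recon"
    recon_dir.mkdir(exist_ok=True)
    for name, result in artifacts.results.items():
        safe = name.replace("+", "_").replace(" ", "_")
        result.final_image.to_nifti(recon_dir / f"{safe}.nii")
        sel = artifacts.manifest["matched_iterations"][name]["iteration"]
        if result.iterates is not None:
            result.iterates[sel - 1].to_nifti(recon_dir / f"{safe}_matched_iter{sel}.nii")
    artifacts.evaluation.per_iteration.to_csv(out_dir / "convergence.csv", index=False)
    artifacts.matched_cr.to_csv(out_dir / "matched_contrast_recovery.csv")
    (out_dir / "manifest.json").write_text(json.dumps(artifacts.manifest, indent=2))


def gibbs_overshoots(
    artifacts: ExperimentArtifacts,
    variants: list[str] | None = None,
    use_noiseless: bool = True,
) -> dict[str, float]:
    """Edge overshoot on the largest sphere at each variant's matched iteration.

    Gibbs ringing is a *systematic* edge artifact; on a single noisy line
    profile the max-based overshoot is dominated by voxel noise (at a 10%
    background working point, hot-sphere voxel maxima sit well above the
    true fill for every variant).  With ``use_noiseless`` the profile is
    therefore taken from a reconstruction of the noiseless realization of
    the same acquisition, run to the matched iteration selected on the noisy
    data — isolating the deterministic overshoot.  Set it to False to probe
    the raw noisy iterates instead.
    """
    from .recon import ReconConfig, VARIANTS as _VARIANTS, reconstruct as _reconstruct

    phantom = artifacts.phantom
    largest = max(phantom.spheres, key=lambda s: s.diameter)
    names = [n for n in artifacts.results if variants is None or n in variants]
    images = {}
    if use_noiseless:
        noiseless = simulate_acquisition(
            phantom,
            artifacts.model,
            artifacts.config.total_counts,
            noiseless=True,
        )
        for name in names:
            sel = artifacts.manifest["matched_iterations"][name]["iteration"]
            prc_mode, psf_enabled, _ = _VARIANTS[name]
            config = ReconConfig(
                n_iterations=sel,
                n_subsets=artifacts.config.n_subsets,
                prc_mode=prc_mode,
                psf_enabled=psf_enabled,
            )
            result = _reconstruct(noiseless, artifacts.model, config)
            images[name] = result.final_image.like(
                result.final_image.values / noiseless.count_scale
            )
    else:
        scale = artifacts.sinogram.count_scale
        for name in names:
            sel = artifacts.manifest["matched_iterations"][name]["iteration"]
            image = artifacts.results[name].iterates[sel - 1]
            images[name] = image.like(image.values / scale)
    return {
        name: edge_overshoot(
            image,
            largest,
            true_activity=largest.activity,
            background_activity=largest.activity / phantom.activity_ratio,
        )
        for name, image in images.items()
    }
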