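"""NIfTI readers/writers, CSV tables and the run configuration file."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError
from .phantom import LabeledHeadVolume, PhantomSpec
from .solver import ConductivityMap, SimulationConfig


def write_labeled_volume(vol: LabeledHeadVolume, path: str | Path) -> None:
    """Write tissue labels as an integer NIfTI-1 with the phantom affine."""
    img = nib.Nifti1Image(vol.labels.astype(np.int16), vol.affine)
    img.header.set_data_dtype(np.int16)
    nib.save(img, str(path))


def read_labeled_volume(path: str | Path) -> LabeledHeadVolume:
    """Read an integer NIfTI-1 label volume; floats are rejected."""
    img = nib.load(str(path))
    dtype = img.get_data_dtype()
    if not np.issubdtype(dtype, np.integer):
        raise FormatError(f"label volume must be integer-typed, got {dtype}")
    data = np.asanyarray(img.dataobj).astype(np.int16)
    aff = img.affine
    scales = np.linalg.norm(aff[:3, :3], axis=0)
    if np.ptp(scales) > 1e-6 * scales.mean():
        import warnings

        warnings.warn("anisotropic affine; using mean voxel size", stacklevel=2)
    return LabeledHeadVolume(data, float(scales.mean()), aff[:3, 3].copy())


def write_field_volume(grid: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a float field (NaN outside the domain) as float32 NIfTI-1."""
    img = nib.Nifti1Image(np.asarray(grid, dtype=np.float32), affine)
    img.header.set_data_dtype(np.float32)
    nib.save(img, str(path))


def read_field_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj).astype(np.float32), img.affine


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """CSV with a stable column order and a plain decimal point."""
    table.to_csv(str(path), index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(str(path))


_KNOWN_KEYS = {
    "seed", "output_dir", "cohort", "phantom", "electrodes", "solver",
    "conductivities", "verbosity",
}
_COHORT_KEYS = {
    "n_subjects", "atrophy_range", "phantom_jitter", "anchor_jitter_sd_mm", "seed",
}
_PHANTOM_KEYS = {
    "grid_shape", "voxel_size_mm", "shell_radii_mm", "atrophy_scale",
    "gm_thickness_mm", "ventricle_radius_mm", "axis_scales", "seed",
}
_ELECTRODE_KEYS = {
    "pad_length_mm", "pad_width_mm", "pad_thickness_mm", "gel_thickness_mm",
    "outward_shift_mm", "tangential_shift_sd_mm", "rotation_sd_deg",
    "area_multiplier_range",
}
_SOLVER_KEYS = {"input_current_A", "solver_tolerance", "max_iterations"}


def load_run_config(path: str | Path) -> dict:
    """Load and validate a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError("run config must be a mapping")
    for section, allowed in (
        (raw, _KNOWN_KEYS),
        (raw.get("cohort", {}), _COHORT_KEYS),
        (raw.get("phantom", {}), _PHANTOM_KEYS),
        (raw.get("electrodes", {}), _ELECTRODE_KEYS),
        (raw.get("solver", {}), _SOLVER_KEYS),
    ):
        unknown = set(section) - allowed if isinstance(section, dict) else set()
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return raw


def build_cohort_config(raw: dict, seed_override: int | None = None):
    """Assemble a CohortConfig from a parsed run-config mapping."""
    from .electrodes import PerturbationSpec
    from .experiment import CohortConfig

    phantom_kwargs = dict(raw.get("phantom", {}))
    for key in ("grid_shape", "shell_radii_mm", "axis_scales"):
        if key in phantom_kwargs:
            phantom_kwargs[key] = tuple(phantom_kwargs[key])
    base_phantom = PhantomSpec(**phantom_kwargs) if phantom_kwargs else PhantomSpec()

    el = dict(raw.get("electrodes", {}))
    pert_kwargs = {
        k: el.pop(k)
        for k in ("outward_shift_mm", "tangential_shift_sd_mm", "rotation_sd_deg",
                  "area_multiplier_range")
        if k in el
    }
    if "area_multiplier_range" in pert_kwargs:
        pert_kwargs["area_multiplier_range"] = tuple(pert_kwargs["area_multiplier_range"])
    perturbation = PerturbationSpec(**pert_kwargs)

    solver_kwargs = dict(raw.get("solver", {}))
    sim = SimulationConfig(**solver_kwargs) if solver_kwargs else SimulationConfig()

    cond = ConductivityMap()
    overrides = raw.get("conductivities", {})
    if overrides:
        cond = cond.with_overrides({int(k): float(v) for k, v in overrides.items()})

    cohort_kwargs = dict(raw.get("cohort", {}))
    if "atrophy_range" in cohort_kwargs:
        cohort_kwargs["atrophy_range"] = tuple(cohort_kwargs["atrophy_range"])
    seed = seed_override if seed_override is not None else raw.get("seed", 0)
    cohort_kwargs.pop("seed", None)
    return CohortConfig(
        base_phantom=base_phantom,
        perturbation=perturbation,
        sim=sim,
        conductivities=cond,
        seed=int(seed),
        **{k: v for k, v in cohort_kwargs.items()
           if k in ("n_subjects", "atrophy_range", "phantom_jitter", "anchor_jitter_sd_mm")},
    )
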