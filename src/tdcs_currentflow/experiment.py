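"""Cohort orchestration: paired artificial/real simulations and the analyses.

For every synthetic subject the same tissue volume is solved twice -- once
with idealized electrode placement and once with perturbed "as-placed"
electrodes -- so any difference in the fields originates solely from the
electrode model.  The per-subject rows are collected into a comparison
table, which feeds the electrode-property and atrophy regressions and the
region-of-interest t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics, stats
from .electrodes import (
    ElectrodeGeometry,
    ElectrodeSpec,
    NAMED_ANCHORS,
    PerturbationSpec,
    compute_contact_area,
    compute_separation_distance,
    normalize_contact_areas,
    place_electrode,
)
from .errors import CurrentFlowError, ValidationError
from .phantom import (
    LabeledHeadVolume,
    PhantomSpec,
    RoiMaskSet,
    RoiSectorConfig,
    compute_volume_ratio,
    define_roi_masks,
    generate_cohort,
)
from .solver import ConductivityMap, SimulationConfig, solve_fields

REGIONS = RoiMaskSet.REGION_NAMES


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort run."""

    n_subjects: int = 16
    atrophy_range: tuple[float, float] = (0.86, 1.0)
    phantom_jitter: float = 0.02
    base_phantom: PhantomSpec = field(default_factory=PhantomSpec)
    anchor_jitter_sd_mm: float = 11.0
    perturbation: PerturbationSpec = field(default_factory=PerturbationSpec)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    conductivities: ConductivityMap = field(default_factory=ConductivityMap)
    roi_sectors: RoiSectorConfig = field(default_factory=RoiSectorConfig)
    pad_length_mm: float = 70.0
    pad_width_mm: float = 50.0
    pad_thickness_mm: float = 3.0
    gel_thickness_mm: float = 3.0
    seed: int = 0


@dataclass
class SubjectResult:
    """One completed paired simulation."""

    subject: int
    spec: PhantomSpec | None
    volume_ratio: float
    medians: dict[str, dict[str, float]]  # model -> region -> median |J|
    areas_cm2: dict[str, tuple[float, float]]  # model -> (anode, cathode)
    separation_cm: dict[str, float]
    geometries: dict[str, tuple[ElectrodeGeometry, ElectrodeGeometry]]
    jmag: dict[str, np.ndarray] | None = None


def _jittered_anchor(direction: np.ndarray, sd_mm: float, radius_mm: float, rng) -> np.ndarray:
    """Rotate a scalp direction by a random tangential offset of scale sd_mm."""
    if sd_mm == 0:
        return direction.copy()
    z = np.array([0.0, 0.0, 1.0])
    t1 = np.cross(z, direction)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(direction, t1)
    # truncated at 2 sd: pads are never misplaced by more than a few cm
    u1, u2 = np.clip(rng.normal(0.0, sd_mm, 2), -2 * sd_mm, 2 * sd_mm)
    disp = t1 * u1 + t2 * u2
    d = direction * radius_mm + disp
    return d / np.linalg.norm(d)


def run_paired_simulation(
    vol: LabeledHeadVolume,
    anode_dir: np.ndarray,
    cathode_dir: np.ndarray,
    config: CohortConfig,
    subject: int = 0,
    subject_seed: int = 0,
    keep_fields: bool = False,
) -> SubjectResult:
    """Solve one subject under both electrode models and summarize.

    The tissue labels (1-5) are verified to be bit-identical across the two
    solves; only the electrode voxels differ.
    """
    rng = np.random.default_rng(subject_seed)
    seeds = rng.integers(0, 2**31 - 1, size=4)

    def _specs(mode: str, s0: int, s1: int):
        common = dict(
            pad_length_mm=config.pad_length_mm,
            pad_width_mm=config.pad_width_mm,
            pad_thickness_mm=config.pad_thickness_mm,
            gel_thickness_mm=config.gel_thickness_mm,
            mode=mode,
            perturbation=config.perturbation,
        )
        return (
            ElectrodeSpec(role="anode", anchor=anode_dir, seed=int(s0), **common),
            ElectrodeSpec(role="cathode", anchor=cathode_dir, seed=int(s1), **common),
        )

    geometries: dict[str, tuple[ElectrodeGeometry, ElectrodeGeometry]] = {}
    volumes: dict[str, LabeledHeadVolume] = {}
    for mode, (sa, sc) in (("artificial", seeds[:2]), ("real", seeds[2:])):
        spec_a, spec_c = _specs(mode, sa, sc)
        v1, geom_a = place_electrode(vol, spec_a)
        v2, geom_c = place_electrode(v1, spec_c)
        geometries[mode] = (geom_a, geom_c)
        volumes[mode] = v2

    tissue_art = np.where(volumes["artificial"].labels <= 5, volumes["artificial"].labels, 0)
    tissue_real = np.where(volumes["real"].labels <= 5, volumes["real"].labels, 0)
    if not np.array_equal(tissue_art, tissue_real):
        raise CurrentFlowError(
            f"subject {subject}: electrode placement altered tissue labels"
        )

    rois = define_roi_masks(
        vol,
        geometries["artificial"][0].anchor_point,
        geometries["artificial"][1].anchor_point,
        config.roi_sectors,
    )
    masks = rois.as_dict()

    medians: dict[str, dict[str, float]] = {}
    areas: dict[str, tuple[float, float]] = {}
    seps: dict[str, float] = {}
    jmags: dict[str, np.ndarray] = {}
    for mode in ("artificial", "real"):
        geom_a, geom_c = geometries[mode]
        v = volumes[mode]
        fields, _, _ = solve_fields(v, geom_a, geom_c, config.conductivities, config.sim)
        medians[mode] = {
            name: metrics.median_current_density(fields.j_magnitude, m, name, mode).median_j
            for name, m in masks.items()
        }
        areas[mode] = (
            compute_contact_area(v, geom_a),
            compute_contact_area(v, geom_c),
        )
        seps[mode] = compute_separation_distance(geom_a, geom_c)
        if keep_fields:
            jmags[mode] = fields.j_magnitude.astype(np.float32)

    return SubjectResult(
        subject=subject,
        spec=None,
        volume_ratio=compute_volume_ratio(vol),
        medians=medians,
        areas_cm2=areas,
        separation_cm=seps,
        geometries=geometries,
        jmag=jmags if keep_fields else None,
    )


@dataclass
class CohortResult:
    """Comparison table plus per-subject records and any failures."""

    table: pd.DataFrame
    subjects: list[SubjectResult]
    failures: list[tuple[int, str]]


def run_cohort_experiment(
    config: CohortConfig | None = None,
    keep_fields: bool = False,
    progress: bool = False,
) -> CohortResult:
    """Run the full paired comparison over a synthetic cohort.

    Deterministic per master seed: phantom geometry, anchor jitter and
    real-mode perturbations all derive from ``config.seed``.  Per-subject
    failures are recorded and the run continues.
    """
    config = config or CohortConfig()
    master = np.random.default_rng(config.seed)
    cohort_seed = int(master.integers(0, 2**31 - 1))
    cohort = generate_cohort(
        config.n_subjects,
        config.atrophy_range,
        config.phantom_jitter,
        seed=cohort_seed,
        base_spec=config.base_phantom,
    )

    results: list[SubjectResult] = []
    failures: list[tuple[int, str]] = []
    scalp_r = config.base_phantom.shell_radii_mm[0]
    for i, (spec, vol) in enumerate(cohort):
        sub_rng = np.random.default_rng(int(master.integers(0, 2**31 - 1)))
        if progress:
            print(f"[cohort] subject {i + 1}/{len(cohort)} atrophy={spec.atrophy_scale:.3f}")
        # a failed placement (e.g. colliding pads) is redrawn with fresh
        # seeded jitter, the way a misplaced pad would be re-stuck
        last_exc: CurrentFlowError | None = None
        for _attempt in range(5):
            anode_dir = _jittered_anchor(
                NAMED_ANCHORS["F4"], config.anchor_jitter_sd_mm, scalp_r, sub_rng
            )
            cathode_dir = _jittered_anchor(
                NAMED_ANCHORS["F3"], config.anchor_jitter_sd_mm, scalp_r, sub_rng
            )
            subject_seed = int(sub_rng.integers(0, 2**31 - 1))
            try:
                res = run_paired_simulation(
                    vol, anode_dir, cathode_dir, config,
                    subject=i + 1, subject_seed=subject_seed, keep_fields=keep_fields,
                )
                res.spec = spec
                results.append(res)
                last_exc = None
                break
            except CurrentFlowError as exc:
                last_exc = exc
        if last_exc is not None:
            failures.append((i + 1, f"{type(last_exc).__name__}: {last_exc}"))

    table = build_comparison_table(results)
    return CohortResult(table=table, subjects=results, failures=failures)


def build_comparison_table(results: list[SubjectResult]) -> pd.DataFrame:
    """One row per subject: volume ratio, electrode properties, medians, PDs."""
    if not results:
        return pd.DataFrame()
    areas_art = np.array([r.areas_cm2["artificial"] for r in results])
    areas_real = np.array([r.areas_cm2["real"] for r in results])
    norm_art, norm_real, _ = normalize_contact_areas(areas_art, areas_real)

    rows = []
    for i, r in enumerate(results):
        row: dict[str, float] = {
            "subject": r.subject,
            "atrophy_scale": r.spec.atrophy_scale if r.spec else np.nan,
            "volume_ratio": r.volume_ratio,
            "area_anode_artificial_cm2": areas_art[i, 0],
            "area_cathode_artificial_cm2": areas_art[i, 1],
            "area_anode_real_cm2": areas_real[i, 0],
            "area_cathode_real_cm2": areas_real[i, 1],
            "normalized_area_artificial": norm_art[i],
            "normalized_area_real": norm_real[i],
            "separation_artificial_cm": r.separation_cm["artificial"],
            "separation_real_cm": r.separation_cm["real"],
        }
        row["pd_separation"] = metrics.percent_difference(
            r.separation_cm["artificial"], r.separation_cm["real"]
        )
        row["pd_area"] = metrics.percent_difference(
            areas_art[i].mean(), areas_real[i].mean()
        )
        for region in REGIONS:
            a = r.medians["artificial"][region]
            b = r.medians["real"][region]
            row[f"j_artificial_{region}"] = a
            row[f"j_real_{region}"] = b
            row[f"pd_{region}"] = metrics.percent_difference(a, b)
        rows.append(row)
    return pd.DataFrame(rows)


def correlate_electrode_properties(
    table: pd.DataFrame,
) -> dict[tuple[str, str], stats.RegressionResult]:
    """OLS of region |J| percent differences on electrode-property PDs."""
    _require_rows(table)
    out: dict[tuple[str, str], stats.RegressionResult] = {}
    for predictor in ("pd_separation", "pd_area"):
        x = table[predictor].to_numpy()
        if np.ptp(x) == 0:
            continue  # constant predictor: skip the whole family
        for region in REGIONS:
            y = table[f"pd_{region}"].to_numpy()
            out[(predictor, region)] = stats.linear_regression(x, y)
    return out


def correlate_atrophy(
    table: pd.DataFrame,
    regions: tuple[str, ...] = ("brain", "gm", "wm"),
) -> dict[tuple[str, str], stats.RegressionResult]:
    """OLS of median |J| on brain volume ratio, per model and brain region."""
    _require_rows(table)
    x = table["volume_ratio"].to_numpy()
    if np.ptp(x) == 0:
        return {}
    out: dict[tuple[str, str], stats.RegressionResult] = {}
    for model in ("artificial", "real"):
        for region in regions:
            y = table[f"j_{model}_{region}"].to_numpy()
            out[(model, region)] = stats.linear_regression(x, y)
    return out


def region_t_tests(table: pd.DataFrame) -> dict[str, stats.TTestResult]:
    """Paired t-tests of real vs artificial median |J| per region."""
    _require_rows(table)
    out = {}
    for region in REGIONS:
        real = table[f"j_real_{region}"].to_numpy()
        art = table[f"j_artificial_{region}"].to_numpy()
        out[region] = stats.paired_t_test(real, art)
    return out


def _require_rows(table: pd.DataFrame, minimum: int = 3) -> None:
    if table is None or len(table) < minimum:
        raise ValidationError(f"comparison table needs at least {minimum} complete rows")
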