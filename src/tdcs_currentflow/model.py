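"""Model/Results objects: the package's primary fitting interface.

``CurrentFlowModel`` wraps one head volume plus an electrode pair and, on
``fit()``, solves the volume-conduction problem and returns a
``CurrentFlowResults`` carrying the field volumes, region summaries and
conservation diagnostics.  ``ElectrodeComparisonStudy`` runs the paired
artificial-vs-real cohort analysis and returns ``StudyResults`` with the
comparison table, regressions and t-tests.  Both mirror the fit/results
split familiar from statistical modelling packages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import experiment, metrics
from .electrodes import (
    ElectrodeGeometry,
    ElectrodeSpec,
    compute_contact_area,
    compute_separation_distance,
    place_electrode,
)
from .phantom import (
    LabeledHeadVolume,
    PhantomSpec,
    RoiSectorConfig,
    define_roi_masks,
    generate_phantom,
)
from .solver import (
    ConductivityMap,
    ConservationReport,
    FieldVolumes,
    SimulationConfig,
    check_current_conservation,
    solve_fields,
)


class CurrentFlowModel:
    """One head volume with an anode/cathode pair, ready to solve."""

    def __init__(
        self,
        volume: LabeledHeadVolume,
        anode: ElectrodeSpec,
        cathode: ElectrodeSpec,
        conductivities: ConductivityMap | None = None,
        config: SimulationConfig | None = None,
    ):
        self.volume = volume
        self.anode_spec = anode
        self.cathode_spec = cathode
        self.conductivities = conductivities or ConductivityMap()
        self.config = config or SimulationConfig()

    @classmethod
    def from_phantom(
        cls,
        spec: PhantomSpec,
        anode: ElectrodeSpec,
        cathode: ElectrodeSpec,
        **kwargs,
    ) -> "CurrentFlowModel":
        return cls(generate_phantom(spec), anode, cathode, **kwargs)

    def fit(self) -> "CurrentFlowResults":
        vol_a, geom_anode = place_electrode(self.volume, self.anode_spec)
        vol_ac, geom_cathode = place_electrode(vol_a, self.cathode_spec)
        fields, system, source = solve_fields(
            vol_ac, geom_anode, geom_cathode, self.conductivities, self.config
        )
        return CurrentFlowResults(
            model=self,
            volume=vol_ac,
            fields=fields,
            system=system,
            source=source,
            geom_anode=geom_anode,
            geom_cathode=geom_cathode,
        )


@dataclass
class CurrentFlowResults:
    """Solved fields plus the electrode geometry actually placed."""

    model: CurrentFlowModel
    volume: LabeledHeadVolume
    fields: FieldVolumes
    system: object
    source: np.ndarray
    geom_anode: ElectrodeGeometry
    geom_cathode: ElectrodeGeometry

    def median_current_density(self, mask: np.ndarray, region: str = "") -> float:
        return metrics.median_current_density(self.fields.j_magnitude, mask, region).median_j

    def contact_areas_cm2(self) -> tuple[float, float]:
        return (
            compute_contact_area(self.volume, self.geom_anode),
            compute_contact_area(self.volume, self.geom_cathode),
        )

    def separation_distance_cm(self) -> float:
        return compute_separation_distance(self.geom_anode, self.geom_cathode)

    def conservation(self, planes: list[tuple[int, int]] | None = None) -> ConservationReport:
        if planes is None:
            mid = self.volume.shape[0] // 2
            planes = [(0, mid)]
        return check_current_conservation(
            self.fields,
            self.volume,
            planes,
            system=self.system,
            source=self.source,
            injected_current=self.model.config.input_current_A,
        )

    def region_summary(self, sectors: RoiSectorConfig | None = None) -> pd.DataFrame:
        rois = define_roi_masks(
            self.model.volume,
            self.geom_anode.anchor_point,
            self.geom_cathode.anchor_point,
            sectors,
        )
        rows = []
        for name, mask in rois.as_dict().items():
            s = metrics.median_current_density(self.fields.j_magnitude, mask, name)
            rows.append({"region": name, "median_j_A_per_m2": s.median_j, "voxels": s.voxel_count})
        return pd.DataFrame(rows)

    def plot_slice(self, path, axis: int = 0, index: int | None = None) -> None:
        """Save a |J| slice image through the head (for quick inspection)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if index is None:
            index = self.volume.shape[axis] // 2
        sl = [slice(None)] * 3
        sl[axis] = index
        img = np.take(self.fields.j_magnitude, index, axis=axis)
        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(img.T, origin="lower", cmap="inferno")
        fig.colorbar(im, ax=ax, label="|J| (A/m$^2$)")
        ax.set_title(f"axis {axis}, slice {index}")
        fig.tight_layout()
        fig.savefig(path, dpi=110)
        plt.close(fig)

    def summary(self) -> str:
        areas = self.contact_areas_cm2()
        rep = self.conservation()
        lines = [
            "Current-flow solve",
            "==================",
            f"grid: {self.volume.shape}, voxel {self.volume.voxel_size_mm} mm",
            f"injected current: {self.model.config.input_current_A * 1e3:.3f} mA",
            f"contact area anode/cathode: {areas[0]:.2f} / {areas[1]:.2f} cm^2",
            f"separation distance: {self.separation_distance_cm():.2f} cm",
            f"solver residual: {rep.residual_relative:.2e}"
            if rep.residual_relative is not None
            else "solver residual: n/a",
        ]
        df = self.region_summary()
        lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


class ElectrodeComparisonStudy:
    """Paired artificial-vs-real electrode comparison on a synthetic cohort."""

    def __init__(self, config: experiment.CohortConfig | None = None):
        self.config = config or experiment.CohortConfig()

    def fit(self, keep_fields: bool = False, progress: bool = False) -> "StudyResults":
        res = experiment.run_cohort_experiment(
            self.config, keep_fields=keep_fields, progress=progress
        )
        return StudyResults(config=self.config, cohort=res)


@dataclass
class StudyResults:
    config: experiment.CohortConfig
    cohort: experiment.CohortResult

    @property
    def table(self) -> pd.DataFrame:
        return self.cohort.table

    def electrode_property_regressions(self):
        return experiment.correlate_electrode_properties(self.table)

    def atrophy_regressions(self):
        return experiment.correlate_atrophy(self.table)

    def roi_t_tests(self):
        return experiment.region_t_tests(self.table)

    def plot_regressions(self, path) -> None:
        """Scatter plots of the atrophy and electrode-distance relationships."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        t = self.table
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for model, marker in (("artificial", "o"), ("real", "D")):
            axes[0].scatter(t["volume_ratio"], t[f"j_{model}_brain"], marker=marker, label=model)
        axes[0].set_xlabel("brain volume ratio")
        axes[0].set_ylabel("median |J| brain (A/m$^2$)")
        axes[0].legend()
        axes[1].scatter(t["pd_separation"], t["pd_whole_head"])
        axes[1].set_xlabel("separation distance PD (%)")
        axes[1].set_ylabel("whole-head |J| PD (%)")
        fig.tight_layout()
        fig.savefig(path, dpi=110)
        plt.close(fig)

    def summary(self) -> str:
        t = self.table
        lines = [
            "Electrode-model comparison study",
            "================================",
            f"subjects: {len(t)} (failures: {len(self.cohort.failures)})",
            f"normalized area artificial: {t.normalized_area_artificial.mean():.2f} "
            f"+/- {t.normalized_area_artificial.std(ddof=1):.2f}",
            f"normalized area real:       {t.normalized_area_real.mean():.2f} "
            f"+/- {t.normalized_area_real.std(ddof=1):.2f}",
            f"separation artificial: {t.separation_artificial_cm.mean():.2f} "
            f"+/- {t.separation_artificial_cm.std(ddof=1):.2f} cm",
            f"separation real:       {t.separation_real_cm.mean():.2f} "
            f"+/- {t.separation_real_cm.std(ddof=1):.2f} cm",
            f"median J brain artificial: {t.j_artificial_brain.mean():.4f} A/m^2",
            f"median J brain real:       {t.j_real_brain.mean():.4f} A/m^2",
        ]
        for (model, region), reg in sorted(self.atrophy_regressions().items()):
            lines.append(
                f"volume_ratio -> J {region} ({model}): slope {reg.slope:+.3f}, "
                f"R^2 {reg.r_squared:.3f}, p {reg.p:.4f}"
            )
        props = self.electrode_property_regressions()
        for key in (("pd_separation", "whole_head"), ("pd_separation", "brain"),
                    ("pd_area", "whole_head"), ("pd_area", "brain")):
            if key in props:
                reg = props[key]
                lines.append(
                    f"{key[0]} -> PD J {key[1]}: slope {reg.slope:+.3f}, "
                    f"R^2 {reg.r_squared:.3f}, p {reg.p:.4f}"
                )
        return "\n".join(lines)
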