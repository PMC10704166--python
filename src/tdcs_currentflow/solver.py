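"""Quasi-static volume-conduction solver: div(sigma grad phi) = 0.

The head is discretized with a finite-volume 7-point stencil on the voxel
grid.  The conductance of the face between neighbouring voxels i and j is
``H(sigma_i, sigma_j) * A_face / d`` with ``H`` the harmonic mean, which is
exact for layered media and keeps the operator symmetric with zero row sums
(discrete conservation).  Voxels with zero conductivity (air/background) are
excluded from the unknowns, so the head surface carries a natural zero-flux
Neumann boundary: injected current cannot leak anywhere except through the
electrode terminals.

Current is injected as a pure Neumann source: +I split uniformly over the
anode pad's outer-face voxels and -I over the cathode's.  The resulting
singular system is solved after grounding one unknown, then gauge-fixed to a
mean-zero potential over the conductive domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import sparse
from scipy.sparse import linalg as spla

from .electrodes import ElectrodeGeometry
from .errors import ConfigurationError, ConnectivityError, PlacementError, SolverError, ValidationError
from .phantom import LABEL_NAMES, LabeledHeadVolume

#: tissue conductivities in S/m.  WM/GM/CSF/bone/skin are the standard
#: literature defaults used by automated current-flow pipelines; the gel
#: value is for conductive paste; the rubber pad value is a typical
#: conductive-rubber figure (configurable).
DEFAULT_CONDUCTIVITIES: dict[int, float] = {
    0: 0.0,      # background / air
    1: 0.126,    # white matter
    2: 0.276,    # gray matter
    3: 1.65,     # CSF
    4: 0.01,     # bone
    5: 0.465,    # skin
    6: 0.3178,   # gel / conductive paste
    7: 0.59,     # electrode rubber pad
}


@dataclass(frozen=True)
class ConductivityMap:
    """Tissue label -> conductivity (S/m); values overridable per run."""

    values: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_CONDUCTIVITIES))

    def with_overrides(self, overrides: dict[int, float]) -> "ConductivityMap":
        merged = dict(self.values)
        merged.update(overrides)
        return ConductivityMap(merged)

    def validate(self) -> None:
        for lab, sig in self.values.items():
            if lab == 0:
                if sig != 0.0:
                    raise ValidationError("background conductivity must be 0")
            elif sig <= 0:
                raise ValidationError(
                    f"conductivity for label {lab} ({LABEL_NAMES.get(lab, '?')}) must be > 0"
                )


@dataclass(frozen=True)
class SimulationConfig:
    """Solver settings: total injected current and convergence control."""

    input_current_A: float = 0.002
    solver_tolerance: float = 1e-10
    max_iterations: int = 20000

    def validate(self) -> None:
        if self.input_current_A <= 0:
            raise ValidationError("input_current_A must be positive")
        if not (0.0 < self.solver_tolerance <= 1e-4):
            raise ValidationError("solver_tolerance must lie in (0, 1e-4]")


@dataclass
class DiscreteSystem:
    """Assembled sparse operator over the conductive voxels."""

    matrix: sparse.csr_matrix  # symmetric, zero row sums
    index_map: np.ndarray  # grid -> unknown index, -1 outside domain
    conductive: np.ndarray  # boolean grid mask
    voxel_size_mm: float
    face_conductance: list[np.ndarray]  # per axis, S, 0 where a side is non-conductive

    @property
    def n_unknowns(self) -> int:
        return int(self.matrix.shape[0])


@dataclass
class FieldVolumes:
    """Potential, electric field and current density on the head grid.

    Values are NaN outside the conductive domain ("no tissue" is distinct
    from "zero field").
    """

    potential: np.ndarray  # V
    e_field: np.ndarray  # (..., 3), V/m
    current_density: np.ndarray  # (..., 3), A/m^2
    j_magnitude: np.ndarray  # A/m^2
    conductive: np.ndarray


@dataclass
class ConservationReport:
    """Discrete current-conservation diagnostics for one solve."""

    plane_fluxes: dict[tuple[int, int], float]
    injected_current: float
    surface_net_flux: float
    residual_relative: float | None

    @property
    def max_plane_deviation(self) -> float:
        if not self.plane_fluxes:
            return 0.0
        return max(abs(abs(f) - self.injected_current) for f in self.plane_fluxes.values())


def build_conductivity_volume(
    vol: LabeledHeadVolume, cmap: ConductivityMap | None = None
) -> np.ndarray:
    """Scalar conductivity grid (S/m) from the tissue labels."""
    cmap = cmap or ConductivityMap()
    cmap.validate()
    labels = vol.labels
    present = np.unique(labels)
    missing = [int(lab) for lab in present if int(lab) not in cmap.values]
    if missing:
        raise ConfigurationError(f"no conductivity assigned for labels {missing}")
    lut = np.zeros(int(present.max()) + 1, dtype=float)
    for lab, sig in cmap.values.items():
        if 0 <= lab < lut.size:
            lut[lab] = sig
    return lut[labels]


def assemble_laplace_system(sigma: np.ndarray, voxel_size_mm: float) -> DiscreteSystem:
    """Finite-volume 7-point operator with harmonic-mean face conductances."""
    if voxel_size_mm <= 0:
        raise ValidationError("voxel_size_mm must be positive")
    sigma = np.asarray(sigma, dtype=float)
    cond = sigma > 0
    n = int(np.count_nonzero(cond))
    if n == 0:
        raise ValidationError("no conductive voxels")
    index_map = np.full(sigma.shape, -1, dtype=np.int64)
    index_map[cond] = np.arange(n)

    h_m = voxel_size_mm * 1e-3  # face area / spacing = h_m^2 / h_m = h_m
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    face_g: list[np.ndarray] = []
    for axis in range(3):
        sl1 = [slice(None)] * 3
        sl2 = [slice(None)] * 3
        sl1[axis] = slice(None, -1)
        sl2[axis] = slice(1, None)
        s1, s2 = sigma[tuple(sl1)], sigma[tuple(sl2)]
        both = cond[tuple(sl1)] & cond[tuple(sl2)]
        g = np.zeros(s1.shape)
        np.divide(2.0 * s1 * s2, s1 + s2, out=g, where=both)
        g *= h_m
        g[~both] = 0.0
        face_g.append(g)
        i = index_map[tuple(sl1)][both]
        j = index_map[tuple(sl2)][both]
        gb = g[both]
        rows.append(i)
        cols.append(j)
        vals.append(-gb)
        rows.append(j)
        cols.append(i)
        vals.append(-gb)
        np.add.at(diag, i, gb)
        np.add.at(diag, j, gb)

    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    matrix = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    return DiscreteSystem(matrix, index_map, cond, voxel_size_mm, face_g)


def _terminal_indices(system: DiscreteSystem, geom: ElectrodeGeometry) -> np.ndarray:
    vox = geom.terminal_voxels
    if vox.size == 0:
        raise PlacementError(f"{geom.role} electrode has no terminal voxels")
    idx = system.index_map[vox[:, 0], vox[:, 1], vox[:, 2]]
    idx = idx[idx >= 0]
    if idx.size == 0:
        raise PlacementError(f"{geom.role} terminal voxels are not conductive")
    return idx


def apply_current_boundary(
    system: DiscreteSystem,
    anode: ElectrodeGeometry,
    cathode: ElectrodeGeometry,
    config: SimulationConfig | None = None,
) -> np.ndarray:
    """Neumann source vector: +I over anode terminals, -I over cathode terminals."""
    config = config or SimulationConfig()
    config.validate()
    ia = _terminal_indices(system, anode)
    ic = _terminal_indices(system, cathode)

    # both terminals must live in one connected conductive component
    comp, _ = ndimage.label(system.conductive)
    ca = comp[tuple(anode.terminal_voxels[0])]
    cc = comp[tuple(cathode.terminal_voxels[0])]
    if ca != cc:
        raise ConnectivityError("anode and cathode lie in disconnected conductive components")

    b = np.zeros(system.n_unknowns)
    current = config.input_current_A
    np.add.at(b, ia, current / ia.size)
    np.add.at(b, ic, -current / ic.size)
    # enforce exact compatibility for the singular Neumann problem; the
    # correction is spread over all terminals so that swapping the roles
    # negates the source exactly
    imbalance = b.sum()
    if imbalance != 0.0:
        terminals = np.concatenate([ia, ic])
        b[terminals] -= imbalance / terminals.size
    return b


def solve_potential(
    system: DiscreteSystem,
    source: np.ndarray,
    config: SimulationConfig | None = None,
) -> np.ndarray:
    """Solve the grounded SPD system, then gauge-fix to a mean-zero potential.

    Returns a potential grid (V) with NaN outside the conductive domain.
    Small systems are solved directly; large ones with conjugate gradients
    preconditioned by an incomplete LU factorization.  Both paths are
    deterministic.
    """
    config = config or SimulationConfig()
    config.validate()
    b = np.asarray(source, dtype=float)
    if b.shape != (system.n_unknowns,):
        raise ValidationError("source vector length does not match the system")

    grid = np.full(system.index_map.shape, np.nan)
    if not np.any(b):
        grid[system.conductive] = 0.0
        return grid

    if abs(b.sum()) > 1e-12 * np.abs(b).max():
        raise ValidationError("source is incompatible (does not sum to zero)")

    # Pure Neumann: the operator is symmetric positive semidefinite with the
    # constant vector in its null space.  With a compatible source, conjugate
    # gradients stays in the range space, so the singular system is solved
    # directly with Jacobi preconditioning; the gauge fixes the free constant.
    A = system.matrix
    diag = A.diagonal()
    if np.any(diag <= 0):
        raise SolverError("non-positive diagonal entry; assembly is inconsistent")
    M = spla.LinearOperator(A.shape, lambda v: v / diag)
    phi, info = spla.cg(
        A, b, rtol=config.solver_tolerance, atol=0.0,
        maxiter=config.max_iterations, M=M,
    )
    resid = np.linalg.norm(A @ phi - b) / np.linalg.norm(b)
    if info != 0 or not np.isfinite(resid):
        raise SolverError(
            f"solve did not converge (info={info}, relative residual {resid:.3e})",
            residual=float(resid),
        )
    phi -= phi.mean()
    grid[system.conductive] = phi
    return grid


def compute_electric_field(
    potential: np.ndarray, voxel_size_mm: float, conductive: np.ndarray | None = None
) -> np.ndarray:
    """E = -grad(phi) in V/m; central differences inside the domain,
    one-sided at domain boundaries, NaN outside."""
    phi = np.asarray(potential, dtype=float)
    if conductive is None:
        conductive = np.isfinite(phi)
    h_m = voxel_size_mm * 1e-3
    phi0 = np.where(conductive, phi, 0.0)
    E = np.zeros(phi.shape + (3,))
    for axis in range(3):
        nxt = np.zeros_like(phi0)
        prv = np.zeros_like(phi0)
        has_nxt = np.zeros_like(conductive)
        has_prv = np.zeros_like(conductive)
        sl_to = [slice(None)] * 3
        sl_from = [slice(None)] * 3
        sl_to[axis] = slice(None, -1)
        sl_from[axis] = slice(1, None)
        nxt[tuple(sl_to)] = phi0[tuple(sl_from)]
        has_nxt[tuple(sl_to)] = conductive[tuple(sl_from)]
        prv[tuple(sl_from)] = phi0[tuple(sl_to)]
        has_prv[tuple(sl_from)] = conductive[tuple(sl_to)]

        grad = np.zeros_like(phi0)
        central = has_nxt & has_prv
        fwd = has_nxt & ~has_prv
        bwd = has_prv & ~has_nxt
        grad[central] = (nxt[central] - prv[central]) / (2.0 * h_m)
        grad[fwd] = (nxt[fwd] - phi0[fwd]) / h_m
        grad[bwd] = (phi0[bwd] - prv[bwd]) / h_m
        E[..., axis] = -grad
    E[~conductive] = np.nan
    return E


def compute_current_density(
    e_field: np.ndarray, sigma: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """J = sigma * E per voxel; returns (J vector grid, |J| grid) in A/m^2."""
    e_field = np.asarray(e_field, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if e_field.shape[:-1] != sigma.shape:
        raise ValidationError("E field and conductivity grids do not match")
    J = sigma[..., None] * e_field
    J[sigma == 0] = 0.0
    mag = np.linalg.norm(J, axis=-1)
    mag[~np.isfinite(e_field).all(axis=-1) & (sigma > 0)] = np.nan
    J[sigma == 0] = np.nan
    mag[sigma == 0] = np.nan
    return J, mag


def solve_fields(
    vol: LabeledHeadVolume,
    anode: ElectrodeGeometry,
    cathode: ElectrodeGeometry,
    cmap: ConductivityMap | None = None,
    config: SimulationConfig | None = None,
) -> tuple[FieldVolumes, DiscreteSystem, np.ndarray]:
    """Convenience pipeline: conductivity -> system -> solve -> E -> J.

    Returns (fields, system, source vector).
    """
    config = config or SimulationConfig()
    sigma = build_conductivity_volume(vol, cmap)
    system = assemble_laplace_system(sigma, vol.voxel_size_mm)
    b = apply_current_boundary(system, anode, cathode, config)
    phi = solve_potential(system, b, config)
    E = compute_electric_field(phi, vol.voxel_size_mm, system.conductive)
    J, mag = compute_current_density(E, sigma)
    fields = FieldVolumes(phi, E, J, mag, system.conductive)
    return fields, system, b


def check_current_conservation(
    fields: FieldVolumes,
    vol: LabeledHeadVolume,
    planes: list[tuple[int, int]],
    system: DiscreteSystem | None = None,
    source: np.ndarray | None = None,
    injected_current: float = 0.002,
) -> ConservationReport:
    """Integrate current flux over cut planes and over the head surface.

    ``planes`` is a list of (axis, index) pairs: the flux is integrated over
    the voxel faces between slice ``index`` and ``index + 1``.  With the
    assembled ``system`` available the flux uses the exact discrete face
    conductances; otherwise the voxel current-density field is averaged onto
    the faces.  The head-surface term sums the outward normal current over
    boundary faces; the discretization carries no flux across zero-
    conductivity faces, so a non-zero value measures numerical error only.
    """
    h_m = vol.voxel_size_mm * 1e-3
    cond = fields.conductive
    phi = fields.potential
    plane_fluxes: dict[tuple[int, int], float] = {}
    for axis, index in planes:
        if not (0 <= index < cond.shape[axis] - 1):
            raise ValidationError(f"plane index {index} out of range for axis {axis}")
        if system is not None:
            g = system.face_conductance[axis]
            sl = [slice(None)] * 3
            sl[axis] = index
            g_plane = g[tuple(sl)]
            sl_a = [slice(None)] * 3
            sl_b = [slice(None)] * 3
            sl_a[axis] = index
            sl_b[axis] = index + 1
            dphi = np.where(
                g_plane > 0,
                np.nan_to_num(phi[tuple(sl_a)]) - np.nan_to_num(phi[tuple(sl_b)]),
                0.0,
            )
            flux = float(np.sum(g_plane * dphi))
        else:
            J_ax = fields.current_density[..., axis]
            sl_a = [slice(None)] * 3
            sl_b = [slice(None)] * 3
            sl_a[axis] = index
            sl_b[axis] = index + 1
            ja = np.nan_to_num(J_ax[tuple(sl_a)])
            jb = np.nan_to_num(J_ax[tuple(sl_b)])
            both = cond[tuple(sl_a)] & cond[tuple(sl_b)]
            flux = float(np.sum(np.where(both, 0.5 * (ja + jb), 0.0)) * h_m**2)
        plane_fluxes[(axis, index)] = flux

    # outward normal current over the voxelized head surface, estimated from
    # the differentiated field (the discrete operator itself carries exactly
    # zero flux across sigma=0 faces)
    Jvec = np.nan_to_num(fields.current_density)
    surface = 0.0
    for axis in range(3):
        for step in (1, -1):
            sl_in = [slice(None)] * 3
            sl_out = [slice(None)] * 3
            if step == 1:
                sl_in[axis] = slice(None, -1)
                sl_out[axis] = slice(1, None)
            else:
                sl_in[axis] = slice(1, None)
                sl_out[axis] = slice(None, -1)
            boundary = cond[tuple(sl_in)] & ~cond[tuple(sl_out)]
            surface += step * float(np.sum(Jvec[..., axis][tuple(sl_in)][boundary])) * h_m**2

    residual = None
    if system is not None and source is not None:
        phi_u = phi[cond]
        r = system.matrix @ phi_u - source
        residual = float(np.linalg.norm(r) / max(np.linalg.norm(source), 1e-300))

    return ConservationReport(
        plane_fluxes=plane_fluxes,
        injected_current=injected_current,
        surface_net_flux=surface,
        residual_relative=residual,
    )
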