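"""Finite-volume solver for Fick's second law on the heterogeneous device.

The concentration field C(x, y, t) obeys

    dC/dt = div( D(x, y) grad C ) + S(x, y)

on a uniform plan-view grid, with zero-flux outer boundaries, a per-material
diffusion coefficient D, a constant distributed source S in the secreting
channel, and an endothelial membrane on the scaffold|lumen interface treated
as a face conductance K (m/s). Daily medium replacement is an instantaneous
reset of one channel's concentration.

Discretisation: cell-centred finite volumes. Interior face transfer
coefficients use the harmonic mean of the adjacent cell diffusivities (the
conservative choice for discontinuous coefficients); the membrane face adds
the series resistance 1/K between the two half-cell resistances. Two time
schemes are provided:

* ``explicit`` - forward-Euler FTCS, stable for dt <= dx^2 / (4 D_max);
* ``implicit`` - backward Euler with a sparse LU factorisation reused across
  steps, unconditionally stable and non-negativity preserving (the system
  matrix is an M-matrix), used for multi-day runs.

Both schemes conserve mass to rounding error on sealed domains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .geometry import (
    DeviceLayout,
    Material,
    DEFAULT_MATERIALS,
    lookup_diffusivity,
)
from .units import M_PER_UM

__all__ = [
    "Grid",
    "ConcentrationField",
    "SourceSpec",
    "ReplacementSchedule",
    "SimulationConfig",
    "SimulationHistory",
    "Profile",
    "ConfigurationError",
    "NumericalFailureError",
    "discretize",
    "step",
    "apply_replacement",
    "run",
    "profile_along_axis",
    "total_mass",
    "stable_dt",
]


class ConfigurationError(ValueError):
    """Raised for inconsistent grids or simulation configurations."""


class NumericalFailureError(RuntimeError):
    """Raised when the solver produces NaN or negative concentrations."""


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Grid:
    """Uniform cell-centred grid over the plan-view domain.

    ``material_map`` and ``region_map`` are (ny, nx) index arrays into
    ``material_names`` / ``region_names``. ``membrane_cols`` lists vertical
    face indices f (between columns f-1 and f) carrying a membrane.
    """

    dx_um: float
    material_map: np.ndarray
    material_names: tuple[str, ...]
    region_map: np.ndarray
    region_names: tuple[str, ...]
    height_um: float
    membrane_cols: tuple[int, ...] = ()
    layout: DeviceLayout | None = None

    @property
    def ny(self) -> int:
        return self.material_map.shape[0]

    @property
    def nx(self) -> int:
        return self.material_map.shape[1]

    @property
    def dx_m(self) -> float:
        return self.dx_um * M_PER_UM

    @property
    def cell_volume_m3(self) -> float:
        return self.dx_m**2 * self.height_um * M_PER_UM

    def x_centers_um(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.dx_um

    def region_mask(self, role: str) -> np.ndarray:
        if role not in self.region_names:
            raise KeyError(f"unknown region role {role!r}")
        idx = self.region_names.index(role)
        mask = self.region_map == idx
        if not mask.any():
            raise KeyError(f"region {role!r} contains no grid cells")
        return mask

    def diffusivity_array(
        self, solute: str, materials: Mapping[str, Material] | None = None
    ) -> np.ndarray:
        """Per-cell diffusion coefficient for ``solute`` (m^2/s)."""
        table = materials
        if table is None:
            table = self.layout.materials if self.layout is not None else DEFAULT_MATERIALS
        d_by_index = np.array(
            [lookup_diffusivity(name, solute, table) for name in self.material_names]
        )
        return d_by_index[self.material_map]

    @classmethod
    def uniform(
        cls,
        width_um: float,
        length_um: float,
        dx_um: float,
        material: str = "medium",
        height_um: float = 150.0,
    ) -> "Grid":
        """Single-material rectangular grid (mainly for solver verification)."""
        nx = int(np.ceil(width_um / dx_um))
        ny = int(np.ceil(length_um / dx_um))
        mmap = np.zeros((ny, nx), dtype=np.int8)
        return cls(
            dx_um=dx_um,
            material_map=mmap,
            material_names=(material,),
            region_map=mmap.copy(),
            region_names=(material,),
            height_um=height_um,
        )

    @classmethod
    def slab(
        cls,
        widths_um: Sequence[float],
        materials: Sequence[str],
        length_um: float,
        dx_um: float,
        height_um: float = 150.0,
    ) -> "Grid":
        """Stacked vertical slabs of different materials (verification aid)."""
        nx_per = [int(np.ceil(w / dx_um)) for w in widths_um]
        ny = int(np.ceil(length_um / dx_um))
        cols = np.concatenate(
            [np.full(n, i, dtype=np.int8) for i, n in enumerate(nx_per)]
        )
        mmap = np.tile(cols, (ny, 1))
        names = tuple(materials)
        return cls(
            dx_um=dx_um,
            material_map=mmap,
            material_names=names,
            region_map=mmap.copy(),
            region_names=names,
            height_um=height_um,
        )


def discretize(
    layout: DeviceLayout, dx_um: float, barrier_mode: str = "interface"
) -> Grid:
    """Discretise a device layout onto a uniform grid.

    ``barrier_mode`` is ``"interface"`` (membrane conductance on the
    scaffold|lumen face, default) or ``"thin_region"`` (the monolayer is
    resolved as a strip of 'barrier' material of the layout's thickness,
    requiring dx <= thickness).
    """
    if not dx_um > 0:
        raise ConfigurationError(f"dx must be > 0, got {dx_um}")
    layout.validate()
    thinnest = min(r.width_um for r in layout.regions)
    if dx_um > thinnest:
        raise ConfigurationError(
            f"dx = {dx_um} um exceeds the thinnest channel width ({thinnest} um)"
        )
    if barrier_mode == "thin_region" and dx_um > layout.barrier.thickness_um:
        raise ConfigurationError(
            f"thin-region barrier mode needs dx <= barrier thickness "
            f"({layout.barrier.thickness_um} um), got dx = {dx_um} um"
        )
    if barrier_mode not in ("interface", "thin_region"):
        raise ConfigurationError(f"unknown barrier mode {barrier_mode!r}")

    nx = int(np.ceil(layout.width_um / dx_um))
    ny = int(np.ceil(layout.length_um / dx_um))
    xc = (np.arange(nx) + 0.5) * dx_um

    region_names = tuple(r.role for r in layout.regions)
    material_names = list(dict.fromkeys(r.material for r in layout.regions))
    region_map = np.empty((1, nx), dtype=np.int8)
    material_row = np.empty(nx, dtype=np.int8)
    for i, r in enumerate(layout.regions):
        inside = (xc >= r.x_range[0]) & (xc < r.x_range[1])
        region_map[0, inside] = i
        material_row[inside] = material_names.index(r.material)
    # cells whose centre falls past the last analytic boundary (ceil padding)
    region_map[0, xc >= layout.width_um] = len(layout.regions) - 1
    material_row[xc >= layout.width_um] = material_names.index(
        layout.regions[-1].material
    )

    membrane_cols: tuple[int, ...] = ()
    if barrier_mode == "interface":
        face = int(round(layout.barrier_interface_x_um / dx_um))
        membrane_cols = (face,)
    else:
        x_if = layout.barrier_interface_x_um
        strip = (xc >= x_if - layout.barrier.thickness_um) & (xc < x_if)
        if "barrier" not in material_names:
            material_names.append("barrier")
        material_row[strip] = material_names.index("barrier")

    material_map = np.tile(material_row, (ny, 1))
    region_map = np.tile(region_map, (ny, 1))
    return Grid(
        dx_um=dx_um,
        material_map=material_map,
        material_names=tuple(material_names),
        region_map=region_map,
        region_names=region_names,
        height_um=layout.height_um,
        membrane_cols=membrane_cols,
        layout=layout,
    )


# ---------------------------------------------------------------------------
# fields and specs
# ---------------------------------------------------------------------------


@dataclass
class ConcentrationField:
    """Solute concentration on a grid at one instant (mol m^-3)."""

    grid: Grid
    values: np.ndarray  # (ny, nx)
    time: float = 0.0

    def validate(self) -> "ConcentrationField":
        if self.values.shape != (self.grid.ny, self.grid.nx):
            raise ConfigurationError(
                f"field shape {self.values.shape} does not match grid "
                f"({self.grid.ny}, {self.grid.nx})"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise NumericalFailureError(
                f"field at t={self.time}s contains NaN/negative values"
            )
        return self

    def copy(self) -> "ConcentrationField":
        return ConcentrationField(self.grid, self.values.copy(), self.time)


@dataclass(frozen=True)
class SourceSpec:
    """Constant distributed volumetric source in one region (mol m^-3 s^-1)."""

    region_role: str
    rate: float

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ConfigurationError(f"source rate must be >= 0, got {self.rate}")


@dataclass(frozen=True)
class ReplacementSchedule:
    """Periodic instantaneous replacement of one channel's contents."""

    region_role: str
    period_s: float
    reset_value: float = 0.0

    def __post_init__(self) -> None:
        if not self.period_s > 0:
            raise ConfigurationError(f"period must be > 0, got {self.period_s}")
        if self.reset_value < 0:
            raise ConfigurationError(
                f"reset value must be >= 0, got {self.reset_value}"
            )


@dataclass
class SimulationConfig:
    """Everything needed to integrate one scenario."""

    layout: DeviceLayout
    solute: str
    dx_um: float
    dt_s: float
    t_end_s: float
    initial_values: Mapping[str, float] = field(default_factory=dict)
    sources: tuple[SourceSpec, ...] = ()
    schedule: tuple[ReplacementSchedule, ...] = ()
    snapshot_interval_s: float = 3600.0
    scheme: str = "implicit"
    barrier_mode: str = "interface"
    membrane_conductance_m_s: float | None = None  # default: layout barrier K
    dirichlet: Mapping[str, float] = field(default_factory=dict)

    def resolved_conductance(self) -> float:
        if self.membrane_conductance_m_s is not None:
            return self.membrane_conductance_m_s
        return self.layout.barrier.conductance_m_s(self.solute)

    def validate(self, grid: Grid | None = None) -> "SimulationConfig":
        if not self.dt_s > 0:
            raise ConfigurationError(f"dt must be > 0, got {self.dt_s}")
        if self.t_end_s < self.dt_s:
            raise ConfigurationError("t_end must be >= dt")
        if self.snapshot_interval_s < self.dt_s:
            raise ConfigurationError("snapshot interval must be >= dt")
        if self.scheme not in ("explicit", "implicit"):
            raise ConfigurationError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "explicit" and grid is not None:
            bound = stable_dt(grid, self.solute)
            if self.dt_s > bound * (1 + 1e-12):
                raise ConfigurationError(
                    f"explicit dt = {self.dt_s}s violates the FTCS stability "
                    f"bound dx^2/(4 D_max) = {bound:.4g}s"
                )
        return self

    def to_dict(self) -> dict:
        return {
            "layout": self.layout.to_dict(),
            "solute": self.solute,
            "dx_um": self.dx_um,
            "dt_s": self.dt_s,
            "t_end_s": self.t_end_s,
            "initial_values": dict(self.initial_values),
            "sources": [
                {"region_role": s.region_role, "rate": s.rate} for s in self.sources
            ],
            "schedule": [
                {
                    "region_role": s.region_role,
                    "period_s": s.period_s,
                    "reset_value": s.reset_value,
                }
                for s in self.schedule
            ],
            "snapshot_interval_s": self.snapshot_interval_s,
            "scheme": self.scheme,
            "barrier_mode": self.barrier_mode,
            "membrane_conductance_m_s": self.membrane_conductance_m_s,
            "dirichlet": dict(self.dirichlet),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        return cls(
            layout=DeviceLayout.from_dict(d["layout"]),
            solute=d["solute"],
            dx_um=d["dx_um"],
            dt_s=d["dt_s"],
            t_end_s=d["t_end_s"],
            initial_values=dict(d.get("initial_values", {})),
            sources=tuple(SourceSpec(**s) for s in d.get("sources", [])),
            schedule=tuple(ReplacementSchedule(**s) for s in d.get("schedule", [])),
            snapshot_interval_s=d.get("snapshot_interval_s", 3600.0),
            scheme=d.get("scheme", "implicit"),
            barrier_mode=d.get("barrier_mode", "interface"),
            membrane_conductance_m_s=d.get("membrane_conductance_m_s"),
            dirichlet=dict(d.get("dirichlet", {})),
        )


def stable_dt(grid: Grid, solute: str, safety: float = 1.0) -> float:
    """FTCS stability bound dt <= dx^2 / (4 D_max)."""
    d_max = float(grid.diffusivity_array(solute).max())
    return safety * grid.dx_m**2 / (4.0 * d_max)


# ---------------------------------------------------------------------------
# operator assembly
# ---------------------------------------------------------------------------


class DiffusionOperator:
    """Face conductances plus explicit/implicit steppers for one grid+solute.

    Face transfer coefficients g (m/s) give a flux density g*(C_j - C_i)
    through each face; the cell balance divides by dx. Zero-flux outer
    boundaries arise naturally from the missing boundary faces.
    """

    def __init__(
        self,
        grid: Grid,
        diffusivity: np.ndarray,
        membrane_conductance: float | Mapping[int, float] | None = None,
        fixed_mask: np.ndarray | None = None,
        fixed_values: np.ndarray | None = None,
    ):
        self.grid = grid
        dx = grid.dx_m
        D = np.asarray(diffusivity, dtype=float)
        if D.shape != (grid.ny, grid.nx):
            raise ConfigurationError("diffusivity array does not match grid shape")

        with np.errstate(divide="ignore"):
            self.gx = 2.0 * D[:, 1:] * D[:, :-1] / (dx * (D[:, 1:] + D[:, :-1]))
            self.gy = 2.0 * D[1:, :] * D[:-1, :] / (dx * (D[1:, :] + D[:-1, :]))

        if grid.membrane_cols:
            if membrane_conductance is None:
                raise ConfigurationError(
                    "grid has membrane faces but no conductance was supplied"
                )
            if not isinstance(membrane_conductance, Mapping):
                membrane_conductance = {
                    c: float(membrane_conductance) for c in grid.membrane_cols
                }
            for col, K in membrane_conductance.items():
                if not 0 < col < grid.nx:
                    raise ConfigurationError(f"membrane face column {col} out of range")
                # series: half-cell + membrane + half-cell resistance
                r_half = dx / (2.0 * D[:, col - 1]) + dx / (2.0 * D[:, col])
                if K <= 0:
                    self.gx[:, col - 1] = 0.0
                else:
                    self.gx[:, col - 1] = 1.0 / (r_half + 1.0 / K)

        self.dx = dx
        self.fixed_mask = fixed_mask
        self.fixed_values = fixed_values
        self._lu_cache: dict[float, object] = {}

    # -- explicit -----------------------------------------------------------

    def explicit_step(
        self, values: np.ndarray, dt: float, source_density: np.ndarray | None
    ) -> np.ndarray:
        C = values
        div = np.zeros_like(C)
        fx = self.gx * (C[:, 1:] - C[:, :-1])
        div[:, :-1] += fx
        div[:, 1:] -= fx
        fy = self.gy * (C[1:, :] - C[:-1, :])
        div[:-1, :] += fy
        div[1:, :] -= fy
        out = C + (dt / self.dx) * div
        if source_density is not None:
            out += dt * source_density
        if self.fixed_mask is not None:
            out[self.fixed_mask] = self.fixed_values[self.fixed_mask]
        return out

    # -- implicit (backward Euler) ------------------------------------------

    def _build_lu(self, dt: float):
        ny, nx = self.grid.ny, self.grid.nx
        n = ny * nx
        idx = np.arange(n).reshape(ny, nx)
        coef = dt / self.dx

        rows, cols, vals = [], [], []

        def add_faces(g, i_idx, j_idx):
            gflat = (coef * g).ravel()
            i = i_idx.ravel()
            j = j_idx.ravel()
            rows.extend([i, i, j, j])
            cols.extend([i, j, j, i])
            vals.extend([gflat, -gflat, gflat, -gflat])

        add_faces(self.gx, idx[:, :-1], idx[:, 1:])
        add_faces(self.gy, idx[:-1, :], idx[1:, :])

        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        L = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        A = sparse.identity(n, format="csr") + L
        if self.fixed_mask is not None:
            fixed = self.fixed_mask.ravel()
            A = A.tolil()
            fixed_rows = np.flatnonzero(fixed)
            for r in fixed_rows:
                A.rows[r] = [r]
                A.data[r] = [1.0]
            A = A.tocsc()
        else:
            A = A.tocsc()
        return splu(A)

    def implicit_step(
        self, values: np.ndarray, dt: float, source_density: np.ndarray | None
    ) -> np.ndarray:
        key = round(float(dt), 9)
        lu = self._lu_cache.get(key)
        if lu is None:
            lu = self._build_lu(dt)
            self._lu_cache[key] = lu
        rhs = values.copy()
        if source_density is not None:
            rhs += dt * source_density
        if self.fixed_mask is not None:
            rhs[self.fixed_mask] = self.fixed_values[self.fixed_mask]
        out = lu.solve(rhs.ravel()).reshape(values.shape)
        return out

    def step(self, values, dt, source_density=None, scheme="explicit"):
        if scheme == "explicit":
            return self.explicit_step(values, dt, source_density)
        if scheme == "implicit":
            return self.implicit_step(values, dt, source_density)
        raise ConfigurationError(f"unknown scheme {scheme!r}")


def _check_values(values: np.ndarray, time: float) -> np.ndarray:
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise NumericalFailureError(
            f"non-finite concentration at t={time:.6g}s, cell (y={bad[0]}, x={bad[1]})"
        )
    scale = float(np.abs(values).max()) or 1.0
    if values.min() < -1e-9 * scale:
        bad = np.argwhere(values == values.min())[0]
        raise NumericalFailureError(
            f"negative concentration {values.min():.3e} at t={time:.6g}s, "
            f"cell (y={bad[0]}, x={bad[1]})"
        )
    return np.maximum(values, 0.0)


def step(
    field: ConcentrationField,
    dt_s: float,
    sources: Sequence[SourceSpec] = (),
    membrane_conductance_m_s: float | None = None,
    solute: str = "abeta",
    scheme: str = "explicit",
) -> ConcentrationField:
    """Advance a field by one time step (convenience wrapper).

    For long runs prefer :func:`run`, which assembles the operator once.
    """
    grid = field.grid
    if scheme == "explicit" and dt_s > stable_dt(grid, solute) * (1 + 1e-12):
        raise ConfigurationError(
            f"dt = {dt_s}s violates the FTCS stability bound "
            f"{stable_dt(grid, solute):.4g}s"
        )
    op = DiffusionOperator(
        grid, grid.diffusivity_array(solute), membrane_conductance_m_s
    )
    src = _source_density(grid, sources)
    out = op.step(field.values, dt_s, src, scheme=scheme)
    out = _check_values(out, field.time + dt_s)
    return ConcentrationField(grid, out, field.time + dt_s)


def _source_density(grid: Grid, sources: Sequence[SourceSpec]) -> np.ndarray | None:
    if not sources:
        return None
    density = np.zeros((grid.ny, grid.nx))
    for s in sources:
        density[grid.region_mask(s.region_role)] += s.rate
    return density


def apply_replacement(
    field: ConcentrationField, region_role: str, reset_value: float
) -> tuple[ConcentrationField, float]:
    """Instantaneously reset one channel; returns (new field, mass removed in mol).

    Mass removed is the pre-event solute content of the channel minus the
    content implied by the reset value (fresh medium carries none by default).
    """
    mask = field.grid.region_mask(region_role)
    vol = field.grid.cell_volume_m3
    removed = float(field.values[mask].sum() * vol - reset_value * mask.sum() * vol)
    out = field.values.copy()
    out[mask] = reset_value
    return ConcentrationField(field.grid, out, field.time), removed


def total_mass(field: ConcentrationField) -> float:
    """Total solute content of the field, in mol."""
    return float(field.values.sum() * field.grid.cell_volume_m3)


# ---------------------------------------------------------------------------
# history
# ---------------------------------------------------------------------------


@dataclass
class Profile:
    """Column-averaged cross-channel concentration profile at one time."""

    position_um: np.ndarray
    concentration_mol_m3: np.ndarray
    time_s: float
    region_boundaries: list[tuple[str, float]]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "position_um": self.position_um,
                "concentration_mol_m3": self.concentration_mol_m3,
            }
        )


@dataclass
class SimulationHistory:
    """Time-ordered snapshots plus the replacement-event log."""

    grid: Grid
    times_s: np.ndarray
    snapshots: np.ndarray  # (n_times, ny, nx)
    events: list[dict]
    config: SimulationConfig | None = None
    source_mass_rate_mol_s: float = 0.0  # total injection rate, bookkeeping

    def snapshot_at(self, t_s: float, atol: float = 1e-6) -> ConcentrationField:
        i = int(np.argmin(np.abs(self.times_s - t_s)))
        if abs(self.times_s[i] - t_s) > max(atol, 1e-9 * max(abs(t_s), 1.0)):
            raise KeyError(
                f"no snapshot at t={t_s}s (nearest: {self.times_s[i]}s); "
                f"history spans [{self.times_s[0]}, {self.times_s[-1]}]s"
            )
        return ConcentrationField(self.grid, self.snapshots[i].copy(), float(self.times_s[i]))

    def region_mean_series(self, role: str) -> tuple[np.ndarray, np.ndarray]:
        mask = self.grid.region_mask(role)
        means = self.snapshots[:, mask].mean(axis=1)
        return self.times_s, means

    def total_mass_series(self) -> np.ndarray:
        return self.snapshots.sum(axis=(1, 2)) * self.grid.cell_volume_m3

    def removed_mass_total(self) -> float:
        return float(sum(e["mass_removed_mol"] for e in self.events))

    # -- persistence --------------------------------------------------------

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("snapshots", data=self.snapshots, dtype="f8")
            f.create_dataset("times", data=self.times_s)
            f.create_dataset("material_map", data=self.grid.material_map)
            f.create_dataset("region_map", data=self.grid.region_map)
            f.attrs["dx_um"] = self.grid.dx_um
            f.attrs["height_um"] = self.grid.height_um
            f.attrs["material_names"] = json.dumps(list(self.grid.material_names))
            f.attrs["region_names"] = json.dumps(list(self.grid.region_names))
            f.attrs["membrane_cols"] = json.dumps(list(self.grid.membrane_cols))
            f.attrs["source_mass_rate_mol_s"] = self.source_mass_rate_mol_s
            if self.config is not None:
                f.attrs["config"] = json.dumps(self.config.to_dict())
            f.attrs["events"] = json.dumps(self.events)

    @classmethod
    def from_hdf5(cls, path) -> "SimulationHistory":
        import h5py

        with h5py.File(path, "r") as f:
            config = None
            if "config" in f.attrs:
                config = SimulationConfig.from_dict(json.loads(f.attrs["config"]))
            grid = Grid(
                dx_um=float(f.attrs["dx_um"]),
                material_map=f["material_map"][...],
                material_names=tuple(json.loads(f.attrs["material_names"])),
                region_map=f["region_map"][...],
                region_names=tuple(json.loads(f.attrs["region_names"])),
                height_um=float(f.attrs["height_um"]),
                membrane_cols=tuple(json.loads(f.attrs["membrane_cols"])),
                layout=config.layout if config is not None else None,
            )
            return cls(
                grid=grid,
                times_s=f["times"][...],
                snapshots=f["snapshots"][...],
                events=json.loads(f.attrs["events"]),
                config=config,
                source_mass_rate_mol_s=float(f.attrs["source_mass_rate_mol_s"]),
            )


def profile_along_axis(history: SimulationHistory, t_s: float) -> Profile:
    """Cross-channel concentration profile (averaged along the channels)."""
    fieldsnap = history.snapshot_at(t_s)
    grid = history.grid
    boundaries: list[tuple[str, float]] = []
    if grid.layout is not None:
        boundaries = grid.layout.region_boundaries_um()
    return Profile(
        position_um=grid.x_centers_um(),
        concentration_mol_m3=fieldsnap.values.mean(axis=0),
        time_s=fieldsnap.time,
        region_boundaries=boundaries,
    )


# ---------------------------------------------------------------------------
# time integration
# ---------------------------------------------------------------------------


def _merge_times(*groups: Sequence[float]) -> np.ndarray:
    all_t = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    all_t = np.unique(np.round(all_t, 6))
    return all_t[all_t >= 0]


def run(config: SimulationConfig) -> SimulationHistory:
    """Integrate a scenario from t=0 to t_end. Fully deterministic.

    Replacement events fire at every multiple of each schedule's period;
    snapshots (taken after any coincident events) are recorded every
    ``snapshot_interval_s`` plus at t=0 and t_end.
    """
    grid = discretize(config.layout, config.dx_um, config.barrier_mode)
    config.validate(grid)

    values = np.zeros((grid.ny, grid.nx))
    for role, c0 in config.initial_values.items():
        if c0 < 0:
            raise ConfigurationError(f"initial value for {role!r} must be >= 0")
        values[grid.region_mask(role)] = c0

    D = grid.diffusivity_array(config.solute)
    membrane = config.resolved_conductance() if grid.membrane_cols else None

    fixed_mask = fixed_values = None
    if config.dirichlet:
        fixed_mask = np.zeros((grid.ny, grid.nx), dtype=bool)
        fixed_values = np.zeros((grid.ny, grid.nx))
        for role, val in config.dirichlet.items():
            m = grid.region_mask(role)
            fixed_mask |= m
            fixed_values[m] = val
        values[fixed_mask] = fixed_values[fixed_mask]

    op = DiffusionOperator(grid, D, membrane, fixed_mask, fixed_values)
    src = _source_density(grid, config.sources)
    source_rate = 0.0
    if src is not None:
        source_rate = float(src.sum() * grid.cell_volume_m3)

    t_end = float(config.t_end_s)
    snap_times = np.arange(0.0, t_end + 1e-9, config.snapshot_interval_s)
    snap_times = _merge_times(snap_times, [t_end])
    event_times = []
    for s in config.schedule:
        grid.region_mask(s.region_role)  # fail fast on unknown regions
        event_times.append(np.arange(s.period_s, t_end + 1e-9, s.period_s))
    checkpoints = _merge_times(snap_times, *event_times) if event_times else snap_times

    snap_set = set(np.round(snap_times, 6))
    events: list[dict] = []
    times_out: list[float] = []
    snaps_out: list[np.ndarray] = []

    t = 0.0
    if 0.0 in snap_set:
        times_out.append(0.0)
        snaps_out.append(values.copy())

    for cp in checkpoints:
        if cp <= 0:
            continue
        seg = cp - t
        n_sub = max(1, int(np.ceil(seg / config.dt_s - 1e-9)))
        dt_sub = seg / n_sub
        for _ in range(n_sub):
            values = op.step(values, dt_sub, src, scheme=config.scheme)
            t += dt_sub
        t = float(cp)
        values = _check_values(values, t)
        # events due at this checkpoint
        for s in config.schedule:
            k = round(t / s.period_s)
            if k >= 1 and abs(t - k * s.period_s) <= 1e-6:
                f = ConcentrationField(grid, values, t)
                f, removed = apply_replacement(f, s.region_role, s.reset_value)
                values = f.values
                events.append(
                    {
                        "time_s": t,
                        "region_role": s.region_role,
                        "reset_value": s.reset_value,
                        "mass_removed_mol": removed,
                    }
                )
        if round(t, 6) in snap_set:
            times_out.append(t)
            snaps_out.append(values.copy())

    return SimulationHistory(
        grid=grid,
        times_s=np.array(times_out),
        snapshots=np.array(snaps_out),
        events=events,
        config=config,
        source_mass_rate_mol_s=source_rate,
    )
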