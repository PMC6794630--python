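"""Plan-view geometry of the five-channel device and its material tables.

The device is a rectangular chip with five parallel microchannels (MCs), in
cross-channel order:

    ren_media_mc | ren_3d_mc | barrier_mc | collagen_scaffold_mc | bec_barrier_mc

``ren_media_mc`` carries neural differentiation medium, ``ren_3d_mc`` the
Matrigel-embedded 3D neural culture, ``barrier_mc`` a 2 mg/mL collagen bridge,
``collagen_scaffold_mc`` the collagen scaffold on whose sidewall the brain
endothelial (bEC) monolayer forms, and ``bec_barrier_mc`` the endothelialized
("luminal") channel. The bEC monolayer is represented as a membrane on the
shared edge of the last two channels, with conductance K = D_b / h_b where
D_b is the barrier diffusion coefficient and h_b its nominal thickness.

Coordinates are micrometres; x runs across the channels starting at 0 on the
outer edge of ``ren_media_mc``, y runs along the channels. Regions are
half-open intervals and must tile the domain exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import yaml

__all__ = [
    "Solute",
    "Material",
    "Region",
    "BarrierSpec",
    "DeviceLayout",
    "LayoutValidationError",
    "MissingParameterError",
    "REGION_ORDER",
    "DEFAULT_SOLUTES",
    "DEFAULT_MATERIALS",
    "build_default_layout",
    "lookup_diffusivity",
]

REGION_ORDER = (
    "ren_media_mc",
    "ren_3d_mc",
    "barrier_mc",
    "collagen_scaffold_mc",
    "bec_barrier_mc",
)

#: Default channel widths across the device, in micrometres. The printed
#: channel dimensions appear only as figure annotations, so these are
#: documented defaults and every acceptance-relevant computation accepts
#: overrides.
DEFAULT_WIDTHS_UM = {
    "ren_media_mc": 1000.0,
    "ren_3d_mc": 1000.0,
    "barrier_mc": 500.0,
    "collagen_scaffold_mc": 1000.0,
    "bec_barrier_mc": 1000.0,
}

DEFAULT_LENGTH_UM = 7500.0
DEFAULT_HEIGHT_UM = 150.0
DEFAULT_BARRIER_THICKNESS_UM = 2.0


class LayoutValidationError(ValueError):
    """Raised when a device layout violates its geometric invariants."""


class MissingParameterError(KeyError):
    """Raised when a (material, solute) diffusivity is not tabulated."""


@dataclass(frozen=True)
class Solute:
    """A diffusing species, identified by name and molecular weight in kDa."""

    name: str
    molecular_weight_kda: float

    def __post_init__(self) -> None:
        if not self.molecular_weight_kda > 0:
            raise ValueError(
                f"molecular weight must be positive, got {self.molecular_weight_kda}"
            )


@dataclass(frozen=True)
class Material:
    """A medium/gel phase with per-solute diffusion coefficients in m^2 s^-1."""

    name: str
    diffusivity: Mapping[str, float]  # solute name -> m^2/s

    def __post_init__(self) -> None:
        for solute, d in self.diffusivity.items():
            if not d > 0:
                raise ValueError(
                    f"diffusivity of {solute!r} in {self.name!r} must be > 0, got {d}"
                )


# Amyloid-beta coefficients are the literature values used by the original
# accumulation scenario. Dextran coefficients are Stokes-Einstein estimates at
# 37 degC (3 kDa ~ 2.0e-10, 40 kDa ~ 6.0e-11 m^2/s in aqueous medium), with
# gel hindrance scaled by the same ratios the amyloid-beta table implies
# (Matrigel 0.689, 2 mg/mL collagen 0.389, scaffold 0.344 of the medium value).
DEFAULT_SOLUTES: dict[str, Solute] = {
    "abeta": Solute("abeta", 4.0),
    "dextran_3kda": Solute("dextran_3kda", 3.0),
    "dextran_40kda": Solute("dextran_40kda", 40.0),
}

DEFAULT_MATERIALS: dict[str, Material] = {
    "medium": Material(
        "medium",
        {"abeta": 1.8e-10, "dextran_3kda": 2.0e-10, "dextran_40kda": 6.0e-11},
    ),
    "matrigel": Material(
        "matrigel",
        {"abeta": 1.24e-10, "dextran_3kda": 1.38e-10, "dextran_40kda": 4.1e-11},
    ),
    "collagen_2mgml": Material(
        "collagen_2mgml",
        {"abeta": 0.7e-10, "dextran_3kda": 0.78e-10, "dextran_40kda": 2.3e-11},
    ),
    # The scaffold was cast at 4 mg/mL; the nearest tabulated coefficient is
    # the 5 mg/mL collagen value, assigned here and overridable in config.
    "collagen_scaffold": Material(
        "collagen_scaffold",
        {"abeta": 0.62e-10, "dextran_3kda": 0.69e-10, "dextran_40kda": 2.1e-11},
    ),
    "barrier": Material("barrier", {"abeta": 2.0e-15}),
}

DEFAULT_REGION_MATERIALS = {
    "ren_media_mc": "medium",
    "ren_3d_mc": "matrigel",
    "barrier_mc": "collagen_2mgml",
    "collagen_scaffold_mc": "collagen_scaffold",
    "bec_barrier_mc": "medium",
}


@dataclass(frozen=True)
class Region:
    """One channel of the plan-view layout (half-open x and y intervals, um)."""

    role: str
    x_range: tuple[float, float]
    y_range: tuple[float, float]
    material: str

    @property
    def width_um(self) -> float:
        return self.x_range[1] - self.x_range[0]

    @property
    def length_um(self) -> float:
        return self.y_range[1] - self.y_range[0]

    def __post_init__(self) -> None:
        if not self.width_um > 0 or not self.length_um > 0:
            raise LayoutValidationError(
                f"region {self.role!r} must have positive extents, got "
                f"x={self.x_range}, y={self.y_range}"
            )


@dataclass(frozen=True)
class BarrierSpec:
    """Endothelial-monolayer barrier on the scaffold|lumen interface.

    The barrier is characterised by a diffusion coefficient per solute and a
    nominal thickness; its membrane conductance for a solute is
    K = D_b / h_b (m/s). Assay simulations may override K directly.
    """

    thickness_um: float = DEFAULT_BARRIER_THICKNESS_UM
    diffusivity: Mapping[str, float] = field(
        default_factory=lambda: {"abeta": 2.0e-15}
    )

    def conductance_m_s(self, solute: str) -> float:
        if solute not in self.diffusivity:
            raise MissingParameterError(
                f"no barrier diffusivity tabulated for solute {solute!r}"
            )
        return self.diffusivity[solute] / (self.thickness_um * 1e-6)


@dataclass(frozen=True)
class DeviceLayout:
    """The five-channel plan-view layout plus material and solute tables."""

    regions: tuple[Region, ...]
    height_um: float
    barrier: BarrierSpec
    materials: Mapping[str, Material] = field(
        default_factory=lambda: dict(DEFAULT_MATERIALS)
    )
    solutes: Mapping[str, Solute] = field(
        default_factory=lambda: dict(DEFAULT_SOLUTES)
    )

    # -- derived geometry ---------------------------------------------------

    @property
    def width_um(self) -> float:
        return self.regions[-1].x_range[1]

    @property
    def length_um(self) -> float:
        return self.regions[0].y_range[1]

    def region(self, role: str) -> Region:
        for r in self.regions:
            if r.role == role:
                return r
        raise KeyError(f"no region with role {role!r}")

    @property
    def barrier_interface_x_um(self) -> float:
        """x position of the bEC monolayer (scaffold | lumen shared edge)."""
        return self.region("collagen_scaffold_mc").x_range[1]

    def region_boundaries_um(self) -> list[tuple[str, float]]:
        """(role, left-edge x) pairs for annotation of cross-channel profiles."""
        return [(r.role, r.x_range[0]) for r in self.regions]

    # -- validation ---------------------------------------------------------

    def validate(self) -> "DeviceLayout":
        roles = [r.role for r in self.regions]
        if roles != list(REGION_ORDER):
            raise LayoutValidationError(
                f"regions must appear in order {REGION_ORDER}, got {roles}"
            )
        if not self.height_um > 0:
            raise LayoutValidationError(f"height must be > 0, got {self.height_um}")
        x = 0.0
        for r in self.regions:
            if abs(r.x_range[0] - x) > 1e-9:
                raise LayoutValidationError(
                    f"regions must tile without gaps/overlap: {r.role!r} starts at "
                    f"{r.x_range[0]} um, expected {x} um"
                )
            x = r.x_range[1]
            if r.y_range != self.regions[0].y_range:
                raise LayoutValidationError(
                    "all channels must span the same y interval"
                )
            if r.material not in self.materials:
                raise LayoutValidationError(
                    f"region {r.role!r} references unknown material {r.material!r}"
                )
        if not self.barrier.thickness_um > 0:
            raise LayoutValidationError("barrier thickness must be > 0")
        scaffold = self.region("collagen_scaffold_mc")
        lumen = self.region("bec_barrier_mc")
        assert scaffold.x_range[1] == lumen.x_range[0]  # guaranteed by tiling
        return self

    def material_at(self, x_um: float, y_um: float) -> str:
        for r in self.regions:
            if r.x_range[0] <= x_um < r.x_range[1] and r.y_range[0] <= y_um < r.y_range[1]:
                return r.material
        raise KeyError(f"point ({x_um}, {y_um}) um outside the device domain")

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "height_um": self.height_um,
            "regions": [
                {
                    "role": r.role,
                    "x_range_um": list(r.x_range),
                    "y_range_um": list(r.y_range),
                    "material": r.material,
                }
                for r in self.regions
            ],
            "barrier": {
                "thickness_um": self.barrier.thickness_um,
                "diffusivity": dict(self.barrier.diffusivity),
            },
            "materials": {
                name: dict(m.diffusivity) for name, m in self.materials.items()
            },
            "solutes": {
                name: s.molecular_weight_kda for name, s in self.solutes.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DeviceLayout":
        regions = tuple(
            Region(
                role=r["role"],
                x_range=tuple(r["x_range_um"]),
                y_range=tuple(r["y_range_um"]),
                material=r["material"],
            )
            for r in d["regions"]
        )
        materials = {
            name: Material(name, dict(diff)) for name, diff in d["materials"].items()
        }
        solutes = {
            name: Solute(name, mw) for name, mw in d["solutes"].items()
        }
        barrier = BarrierSpec(
            thickness_um=d["barrier"]["thickness_um"],
            diffusivity=dict(d["barrier"]["diffusivity"]),
        )
        return cls(
            regions=regions,
            height_um=d["height_um"],
            barrier=barrier,
            materials=materials,
            solutes=solutes,
        ).validate()

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "DeviceLayout":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "DeviceLayout":
        return cls.from_dict(json.loads(text))


def build_default_layout(
    widths_um: Mapping[str, float] | None = None,
    length_um: float = DEFAULT_LENGTH_UM,
    height_um: float = DEFAULT_HEIGHT_UM,
    barrier_thickness_um: float = DEFAULT_BARRIER_THICKNESS_UM,
    barrier_diffusivity: Mapping[str, float] | None = None,
    region_materials: Mapping[str, str] | None = None,
    materials: Mapping[str, Material] | None = None,
    solutes: Mapping[str, Solute] | None = None,
) -> DeviceLayout:
    """Build the default five-channel layout, with optional overrides.

    ``widths_um`` may override any subset of channel widths; the domain width
    grows or shrinks by exactly the sum of the deltas (channels tile).
    """
    w = dict(DEFAULT_WIDTHS_UM)
    if widths_um:
        unknown = set(widths_um) - set(w)
        if unknown:
            raise LayoutValidationError(f"unknown region roles in widths: {unknown}")
        w.update(widths_um)
    mats = dict(materials if materials is not None else DEFAULT_MATERIALS)
    sols = dict(solutes if solutes is not None else DEFAULT_SOLUTES)
    region_mats = dict(DEFAULT_REGION_MATERIALS)
    if region_materials:
        region_mats.update(region_materials)

    regions = []
    x = 0.0
    for role in REGION_ORDER:
        width = w[role]
        if not width > 0:
            raise LayoutValidationError(
                f"width of {role!r} must be > 0, got {width}"
            )
        regions.append(
            Region(
                role=role,
                x_range=(x, x + width),
                y_range=(0.0, length_um),
                material=region_mats[role],
            )
        )
        x += width

    barrier = BarrierSpec(
        thickness_um=barrier_thickness_um,
        diffusivity=dict(
            barrier_diffusivity
            if barrier_diffusivity is not None
            else DEFAULT_MATERIALS["barrier"].diffusivity
        ),
    )
    return DeviceLayout(
        regions=tuple(regions),
        height_um=height_um,
        barrier=barrier,
        materials=mats,
        solutes=sols,
    ).validate()


def lookup_diffusivity(
    material: str | Material,
    solute: str | Solute,
    materials: Mapping[str, Material] | None = None,
) -> float:
    """Diffusion coefficient of ``solute`` in ``material`` (m^2 s^-1).

    Raises :class:`MissingParameterError` naming both keys if untabulated.
    """
    table = materials if materials is not None else DEFAULT_MATERIALS
    if isinstance(material, str):
        if material not in table:
            raise MissingParameterError(f"unknown material {material!r}")
        mat = table[material]
    else:
        mat = material
    sname = solute if isinstance(solute, str) else solute.name
    if sname not in mat.diffusivity:
        raise MissingParameterError(
            f"no diffusivity tabulated for solute {sname!r} in material {mat.name!r}"
        )
    return mat.diffusivity[sname]
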