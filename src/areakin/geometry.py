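"""Compartment geometry primitives.

Conversions between cross-section, radius, volume and surface area for
spherical organelles (nuclei) and cuboid plant cells, plus the generic
:class:`CompartmentGeometry` record consumed by the kinetic-model layer.

Unit conventions, fixed package-wide: lengths in µm, areas in µm²,
volumes in µm³ (1 µm³ = 1 fL), concentrations in µmol/L (µM), time in s.
With these choices one "amount unit" is 1 µM·µm³ = 1e-21 mol, and
area-scaled first-order rate constants carry units of µm·s⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .errors import GeometryError

__all__ = [
    "SphereGeometry",
    "CuboidGeometry",
    "CompartmentGeometry",
    "sphere_from_cross_section",
    "sphere_from_volume",
    "scale_sphere",
    "root_cell_geometry",
    "load_geometry_config",
]

#: moles per internal amount unit (1 µM · 1 µm³)
AMOUNT_UNIT_IN_MOL = 1e-21


def _require_positive(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0.0:
        raise GeometryError(f"{name} must be a positive finite number, got {value!r}")
    return value


@dataclass(frozen=True)
class SphereGeometry:
    """A perfect sphere of radius ``radius`` (µm).

    Volume, surface area and great-circle cross-section are derived
    properties and therefore mutually consistent by construction; in
    particular ``surface_area == 4 * cross_section`` exactly.
    """

    radius: float

    def __post_init__(self) -> None:
        r = float(self.radius)
        if not math.isfinite(r) or r < 0.0:
            raise GeometryError(f"sphere radius must be >= 0, got {r!r}")
        object.__setattr__(self, "radius", r)

    @property
    def volume(self) -> float:
        """(4/3)·π·r³ in µm³."""
        return 4.0 / 3.0 * math.pi * self.radius**3

    @property
    def surface_area(self) -> float:
        """4·π·r² in µm²."""
        return 4.0 * math.pi * self.radius**2

    @property
    def cross_section(self) -> float:
        """Great-circle cross-section π·r² in µm²."""
        return math.pi * self.radius**2

    def to_compartment(self, interface: str = "surface") -> "CompartmentGeometry":
        """Wrap as a :class:`CompartmentGeometry` whose single membrane area
        is the sphere surface, registered under ``interface``."""
        if self.radius <= 0.0:
            raise GeometryError("cannot build a compartment from a zero-radius sphere")
        return CompartmentGeometry(
            volume=self.volume,
            membrane_areas={interface: self.surface_area},
            provenance=f"sphere(r={self.radius:g})",
        )


def sphere_from_cross_section(cross_section: float) -> SphereGeometry:
    """Sphere whose great-circle cross-section (µm²) is given.

    This is the conversion used for nuclei measured in 2D micrographs:
    the visible nuclear cross-section is taken as the great circle, so
    ``r = sqrt(A_cs / π)``; volume and surface follow from the radius.
    """
    cs = _require_positive("cross_section", cross_section)
    return SphereGeometry(radius=math.sqrt(cs / math.pi))


def sphere_from_volume(volume: float) -> SphereGeometry:
    """Sphere of the given volume (µm³); ``r = (3V / 4π)^(1/3)``."""
    v = _require_positive("volume", volume)
    return SphereGeometry(radius=(3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0))


def scale_sphere(sphere: SphereGeometry, radius_factor: float) -> SphereGeometry:
    """Scale a sphere's radius by ``radius_factor`` (> 0).

    Surface area scales by the square and volume by the cube of the factor.
    """
    f = _require_positive("radius_factor", radius_factor)
    return SphereGeometry(radius=sphere.radius * f)


@dataclass(frozen=True)
class CuboidGeometry:
    """A rectangular box: the idealized plant root cell.

    Root epidermis cells grow almost exclusively in length while width and
    depth stay near constant, so the face shared with the axially adjacent
    cell (``width * depth``) barely changes as the cell elongates.
    """

    length: float
    width: float
    depth: float

    def __post_init__(self) -> None:
        for name in ("length", "width", "depth"):
            object.__setattr__(self, name, _require_positive(name, getattr(self, name)))

    @property
    def volume(self) -> float:
        return self.length * self.width * self.depth

    @property
    def vertical_interface_area(self) -> float:
        """Area of the face shared with the axially adjacent cell (µm²)."""
        return self.width * self.depth

    @property
    def total_surface_area(self) -> float:
        l, w, d = self.length, self.width, self.depth
        return 2.0 * (l * w + l * d + w * d)

    def to_compartment(self) -> "CompartmentGeometry":
        return CompartmentGeometry(
            volume=self.volume,
            membrane_areas={
                "vertical_interface": self.vertical_interface_area,
                "total_surface": self.total_surface_area,
            },
            provenance=f"cuboid(L={self.length:g}, w={self.width:g}, d={self.depth:g})",
        )


@dataclass(frozen=True)
class CompartmentGeometry:
    """Volume plus named membrane/interface areas of one compartment.

    ``provenance`` records the shape the values were derived from, or
    ``"direct"`` when volume and areas were supplied as bare numbers.
    """

    volume: float
    membrane_areas: Mapping[str, float] = field(default_factory=dict)
    provenance: str = "direct"

    def __post_init__(self) -> None:
        object.__setattr__(self, "volume", _require_positive("volume", self.volume))
        areas = {}
        for name, area in dict(self.membrane_areas).items():
            areas[str(name)] = _require_positive(f"membrane area {name!r}", area)
        # plain dict (not a mapping proxy) so models containing geometries
        # stay deep-copyable; treat as read-only
        object.__setattr__(self, "membrane_areas", areas)

    def area(self, interface: str) -> float:
        try:
            return self.membrane_areas[interface]
        except KeyError:
            raise GeometryError(
                f"no interface {interface!r} in compartment geometry "
                f"(available: {sorted(self.membrane_areas)})"
            ) from None

    def scaled(self, volume_factor: float = 1.0, area_factor: float = 1.0) -> "CompartmentGeometry":
        """Geometry with volume and all areas multiplied by the given factors."""
        _require_positive("volume_factor", volume_factor)
        _require_positive("area_factor", area_factor)
        return CompartmentGeometry(
            volume=self.volume * volume_factor,
            membrane_areas={k: v * area_factor for k, v in self.membrane_areas.items()},
            provenance=f"{self.provenance} * (V x{volume_factor:g}, A x{area_factor:g})",
        )


def root_cell_geometry(length: float, width: float, depth: float) -> CompartmentGeometry:
    """Cuboid root-cell geometry with its two named interfaces.

    ``vertical_interface`` (= width·depth) is the contact face with the
    axially adjacent cell and stays constant while the cell elongates;
    volume grows linearly in ``length`` with slope width·depth.
    """
    return CuboidGeometry(length=length, width=width, depth=depth).to_compartment()


def _compartment_from_spec(name: str, spec: Mapping) -> CompartmentGeometry:
    if not isinstance(spec, Mapping):
        raise GeometryError(f"geometry entry {name!r} must be a mapping, got {spec!r}")
    shape = spec.get("shape")
    if shape == "sphere":
        if "radius" in spec:
            sphere = SphereGeometry(radius=_require_positive("radius", spec["radius"]))
        elif "cross_section" in spec:
            sphere = sphere_from_cross_section(spec["cross_section"])
        elif "volume" in spec:
            sphere = sphere_from_volume(spec["volume"])
        else:
            raise GeometryError(
                f"sphere entry {name!r} needs one of radius/cross_section/volume"
            )
        return sphere.to_compartment()
    if shape == "cuboid":
        try:
            return root_cell_geometry(spec["L"], spec["w"], spec["d"])
        except KeyError as exc:
            raise GeometryError(f"cuboid entry {name!r} needs L, w and d") from exc
    if shape is None:
        if "volume" not in spec:
            raise GeometryError(f"direct entry {name!r} needs a volume")
        return CompartmentGeometry(
            volume=spec["volume"],
            membrane_areas=dict(spec.get("areas", {})),
        )
    raise GeometryError(f"unknown shape {shape!r} for entry {name!r}")


def load_geometry_config(path) -> dict[str, CompartmentGeometry]:
    """Read a per-compartment geometry table from a YAML file.

    Each top-level key names a compartment and maps to either
    ``{shape: sphere, radius|cross_section|volume: ...}``,
    ``{shape: cuboid, L: ..., w: ..., d: ...}`` or
    ``{volume: ..., areas: {name: value, ...}}``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise GeometryError(f"geometry config {path} must be a mapping of compartments")
    return {str(name): _compartment_from_spec(str(name), spec) for name, spec in raw.items()}
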