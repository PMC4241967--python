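"""Axon-bundle composition, sample-volume geometry and sodium-channel counts.

A fiber tract is modelled as a discrete set of axon classes (diameter, count,
myelination) packed as parallel cylinders in a cubic sample volume.  Myelinated
axons expose sodium channels only at nodes of Ranvier (short unmyelinated gaps
spaced proportionally to the axon diameter); unmyelinated axons expose channels
over their whole membrane.  These counts feed the trans-membrane water-flux
model in :mod:`idti.flux`.

Internal lengths are micrometres; constructors accept the conventional units
(sample lengths in mm, diameters in um) and convert at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "AxonClass",
    "BundleGeometry",
    "ChannelBiophysics",
    "AxonBundle",
    "ChannelCounts",
    "nodes_per_axon",
    "node_surface_area",
    "unmyelinated_membrane_area",
    "channel_count_myelinated",
    "channel_count_unmyelinated",
    "sample_volume_side",
    "water_mass_in_volume",
    "corticospinal_bundle",
    "load_bundle",
    "bundle_table",
]

_UM_PER_MM = 1e3


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise InvalidParameterError(f"{name} must be > 0, got {value!r}")


def _require_nonnegative(name: str, value: float) -> None:
    if value < 0:
        raise InvalidParameterError(f"{name} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class AxonClass:
    """One diameter class of a fiber tract.

    Parameters
    ----------
    diameter_um : float
        Axon diameter in micrometres.
    count : int
        Number of axons of this class in the tract.
    myelinated : bool
        Whether the class conducts saltatorily (channels at nodes of Ranvier
        only) or continuously (channels over the whole membrane).
    fraction : float, optional
        Informational fraction of the tract this class represents.
    """

    diameter_um: float
    count: int
    myelinated: bool
    fraction: float | None = None

    def __post_init__(self) -> None:
        _require_positive("diameter_um", self.diameter_um)
        if self.count < 0:
            raise InvalidParameterError(f"count must be >= 0, got {self.count!r}")
        if self.fraction is not None and not 0 <= self.fraction <= 1:
            raise InvalidParameterError(
                f"fraction must lie in [0, 1], got {self.fraction!r}"
            )


@dataclass(frozen=True)
class BundleGeometry:
    """Geometry of the cubic sample volume containing the tract.

    ``internodal_ratio`` sets the internodal distance as a multiple of the
    axon diameter (default 100x); ``interaxonal_space_fraction`` is the void
    fraction of a square-lattice packing of cylinders (default 17%).
    """

    sample_length_mm: float = 3.5
    node_length_um: float = 2.0
    internodal_ratio: float = 100.0
    interaxonal_space_fraction: float = 0.17

    def __post_init__(self) -> None:
        _require_positive("sample_length_mm", self.sample_length_mm)
        _require_positive("node_length_um", self.node_length_um)
        _require_positive("internodal_ratio", self.internodal_ratio)
        if not 0 <= self.interaxonal_space_fraction < 1:
            raise InvalidParameterError(
                "interaxonal_space_fraction must lie in [0, 1), got "
                f"{self.interaxonal_space_fraction!r}"
            )

    @property
    def sample_length_um(self) -> float:
        return self.sample_length_mm * _UM_PER_MM


@dataclass(frozen=True)
class ChannelBiophysics:
    """Sodium-channel densities and per-channel ion/water transport rates.

    ``rho_node`` is the areal channel density at nodes of Ranvier,
    ``rho_unmyelinated`` over unmyelinated membrane (both channels/um^2).
    ``ion_flux_per_channel`` is sodium ions per millisecond through one open
    channel; ``waters_per_na`` the water molecules dragged per sodium ion.
    ``waters_per_k`` (potassium counter-flow) is retained for reference but
    does not enter the flux arithmetic: mass balance fixes the outward water
    flow equal to the inward one.
    """

    rho_node: float = 10_000.0
    rho_unmyelinated: float = 200.0
    ion_flux_per_channel: float = 8.8e3
    waters_per_na: float = 2.5
    waters_per_k: float = 1.15

    def __post_init__(self) -> None:
        for name in (
            "rho_node",
            "rho_unmyelinated",
            "ion_flux_per_channel",
            "waters_per_na",
            "waters_per_k",
        ):
            _require_nonnegative(name, getattr(self, name))


@dataclass(frozen=True)
class AxonBundle:
    """An ordered collection of axon classes plus sample-volume geometry."""

    classes: tuple[AxonClass, ...]
    geometry: BundleGeometry = field(default_factory=BundleGeometry)

    def __post_init__(self) -> None:
        if not self.classes:
            raise InvalidParameterError("bundle must contain at least one axon class")
        object.__setattr__(self, "classes", tuple(self.classes))
        fractions = [c.fraction for c in self.classes if c.fraction is not None]
        if len(fractions) == len(self.classes) and fractions:
            total = sum(fractions)
            if abs(total - 1.0) > 1e-6 + 5e-4 * len(fractions):
                # fractions are informational and rounded in published tables;
                # allow rounding slack proportional to the class count
                raise InvalidParameterError(
                    f"class fractions sum to {total}, expected 1"
                )

    @property
    def myelinated(self) -> tuple[AxonClass, ...]:
        return tuple(c for c in self.classes if c.myelinated)

    @property
    def unmyelinated(self) -> tuple[AxonClass, ...]:
        return tuple(c for c in self.classes if not c.myelinated)

    @property
    def n_axons(self) -> int:
        return sum(c.count for c in self.classes)


def nodes_per_axon(diameter_um: float, geometry: BundleGeometry) -> float:
    """Average number of nodes of Ranvier per axon crossing the sample volume.

    The internodal distance is ``internodal_ratio * diameter``; the count is
    the sample edge length divided by it and is deliberately fractional — it
    is a population average, not a per-cell integer.
    """
    _require_positive("diameter_um", diameter_um)
    return geometry.sample_length_um / (geometry.internodal_ratio * diameter_um)


def node_surface_area(diameter_um: float, node_length_um: float = 2.0) -> float:
    """Membrane area of one node of Ranvier in um^2.

    Modelled as the lateral surface of an open cylinder (no end caps):
    pi * diameter * node_length.
    """
    _require_positive("diameter_um", diameter_um)
    _require_positive("node_length_um", node_length_um)
    return math.pi * diameter_um * node_length_um


def unmyelinated_membrane_area(diameter_um: float, sample_length_mm: float) -> float:
    """Membrane area (um^2) of an unmyelinated axon spanning the sample volume."""
    _require_positive("diameter_um", diameter_um)
    _require_positive("sample_length_mm", sample_length_mm)
    return math.pi * diameter_um * sample_length_mm * _UM_PER_MM


@dataclass(frozen=True)
class ChannelCounts:
    """Per-class and total sodium-channel counts for one membrane type."""

    per_class: tuple[float, ...]
    total: float


def channel_count_myelinated(
    bundle: AxonBundle, chans: ChannelBiophysics
) -> ChannelCounts:
    """Sodium channels at nodes of Ranvier, per myelinated class and total.

    Per class: count x nodes_per_axon x node_area x rho_node.  A bundle with
    no myelinated class yields a zero total.
    """
    geom = bundle.geometry
    per_class = tuple(
        c.count
        * nodes_per_axon(c.diameter_um, geom)
        * node_surface_area(c.diameter_um, geom.node_length_um)
        * chans.rho_node
        for c in bundle.myelinated
    )
    return ChannelCounts(per_class=per_class, total=sum(per_class))


def channel_count_unmyelinated(
    bundle: AxonBundle, chans: ChannelBiophysics
) -> ChannelCounts:
    """Sodium channels over unmyelinated membrane, per class and total."""
    geom = bundle.geometry
    per_class = tuple(
        c.count
        * unmyelinated_membrane_area(c.diameter_um, geom.sample_length_mm)
        * chans.rho_unmyelinated
        for c in bundle.unmyelinated
    )
    return ChannelCounts(per_class=per_class, total=sum(per_class))


def sample_volume_side(bundle: AxonBundle) -> float:
    """Edge (mm) of the cube whose cross-section holds the packed tract.

    The summed axon cross-sections are inflated by the interaxonal void
    fraction of a square-lattice packing, then the square root gives the side.
    """
    f = bundle.geometry.interaxonal_space_fraction
    if f >= 1:
        raise InvalidParameterError("interaxonal_space_fraction must be < 1")
    cross_section_um2 = sum(
        c.count * math.pi * (c.diameter_um / 2) ** 2 for c in bundle.classes
    )
    side_um = math.sqrt(cross_section_um2 / (1.0 - f))
    return side_um / _UM_PER_MM


def water_mass_in_volume(
    side_mm: float, water_fraction: float = 0.9, tissue_density_g_cm3: float = 1.0
) -> float:
    """Mass of water (g) in a cubic sample volume of the given edge length."""
    _require_positive("side_mm", side_mm)
    if not 0 <= water_fraction <= 1:
        raise InvalidParameterError(
            f"water_fraction must lie in [0, 1], got {water_fraction!r}"
        )
    _require_nonnegative("tissue_density_g_cm3", tissue_density_g_cm3)
    volume_cm3 = side_mm**3 * 1e-3  # mm^3 -> cm^3
    return volume_cm3 * tissue_density_g_cm3 * water_fraction


# Built-in corticospinal-tract composition: ~10^6 axons, 70% myelinated
# across four diameter classes, 30% unmyelinated at 3 um.
_CST_ROWS: tuple[tuple[float, int, bool, float], ...] = (
    (2.0, 567_000, True, 0.550),
    (5.0, 105_000, True, 0.102),
    (8.0, 28_000, True, 0.027),
    (11.0, 30_000, True, 0.029),
    (3.0, 300_000, False, 0.291),
)


def corticospinal_bundle(geometry: BundleGeometry | None = None) -> AxonBundle:
    """The default corticospinal-tract bundle (hand representation)."""
    classes = tuple(
        AxonClass(diameter_um=d, count=n, myelinated=m, fraction=f)
        for d, n, m, f in _CST_ROWS
    )
    return AxonBundle(classes=classes, geometry=geometry or BundleGeometry())


def load_bundle(
    path: str | Path, geometry: BundleGeometry | None = None
) -> AxonBundle:
    """Read a bundle from a delimited text file.

    Expects columns ``diameter_um``, ``count``, ``myelinated`` (and an
    optional ``fraction``); the delimiter is sniffed by pandas.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"diameter_um", "count", "myelinated"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidParameterError(
            f"bundle file {path} missing columns: {sorted(missing)}"
        )
    classes = []
    for row in df.itertuples(index=False):
        myel = row.myelinated
        if isinstance(myel, str):
            myel = myel.strip().lower() in {"true", "1", "yes"}
        frac = getattr(row, "fraction", None)
        classes.append(
            AxonClass(
                diameter_um=float(row.diameter_um),
                count=int(row.count),
                myelinated=bool(myel),
                fraction=None if frac is None or pd.isna(frac) else float(frac),
            )
        )
    return AxonBundle(classes=tuple(classes), geometry=geometry or BundleGeometry())


def bundle_table(bundle: AxonBundle, chans: ChannelBiophysics) -> pd.DataFrame:
    """Tabular summary of the bundle, one row per class.

    Mirrors the conventional published layout: axon count, diameter, node
    area (myelinated classes) and total sodium channels per class.
    """
    geom = bundle.geometry
    rows = []
    for c in bundle.classes:
        if c.myelinated:
            area = node_surface_area(c.diameter_um, geom.node_length_um)
            channels = (
                c.count * nodes_per_axon(c.diameter_um, geom) * area * chans.rho_node
            )
        else:
            area = float("nan")
            channels = (
                c.count
                * unmyelinated_membrane_area(c.diameter_um, geom.sample_length_mm)
                * chans.rho_unmyelinated
            )
        rows.append(
            {
                "type": "myelinated" if c.myelinated else "unmyelinated",
                "n_axons": c.count,
                "diameter_um": c.diameter_um,
                "node_area_um2": area,
                "na_channels": channels,
            }
        )
    return pd.DataFrame(rows)
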